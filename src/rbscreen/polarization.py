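"""Stokes/Mueller model of the double-pass scanning polarimeter.

The instrument launches horizontally polarized light through a spinning
half-wave plate (HWP, at 9/16 of the scan rate), an optional fixed wave
plate, and the cornea; the beam lands on the retina at a point moving around
a circle of 1.5 deg radius, where the radially oriented, birefringent Henle
fibers act as a weak retarder whose axis rotates with the scan. Light
specularly reflected by the fundus retraces the train, and a polarizing
beam splitter routes only the polarization-changed (vertical) component to
the detector.

Conventions
-----------
* Angles in degrees. Azimuths counter-clockwise from horizontal, viewed
  against propagation; scan angle phi = 0 at the +x retinal direction.
* Stokes vectors (s0, s1, s2, s3) with s1 = horizontal minus vertical.
* The fundus reflection is modeled as the identity Mueller matrix and the
  return HWP pass uses the same azimuth and handedness as the forward pass
  (single folded coordinate frame). Among the candidate double-pass
  conventions this is the one that puts the gaze-independent carrier at
  4.5 f_s with a corneal-retardance-dependent split between the 2.5 and
  6.5 f_s fixation sidebands, matching the behavior of the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import InvalidGeometryError, ScanConfig

__all__ = [
    "Retarder",
    "EyeOptics",
    "rotator_matrix",
    "retarder_matrix",
    "henle_axis",
    "detector_sample",
    "detector_signal",
    "stokes",
]


def stokes(s0: float, s1: float, s2: float, s3: float) -> np.ndarray:
    """Build a Stokes vector, checking physicality (s1^2+s2^2+s3^2 <= s0^2)."""
    v = np.array([s0, s1, s2, s3], dtype=float)
    if s0 < 0 or s1 * s1 + s2 * s2 + s3 * s3 > s0 * s0 * (1 + 1e-12):
        raise ValueError("unphysical Stokes vector")
    return v


@dataclass(frozen=True)
class Retarder:
    """Linear retarder: phase retardance and fast-axis azimuth, in degrees."""

    retardance_deg: float
    axis_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "retardance_deg", float(self.retardance_deg) % 360.0)
        object.__setattr__(self, "axis_deg", float(self.axis_deg) % 180.0)


@dataclass(frozen=True)
class EyeOptics:
    """Per-eye optical parameters of the simulated subject.

    ``henle_retardance_deg`` is the single-pass retardance of the Henle fiber
    layer at the 3-degree-diameter scan circle; ``fixation_offset_deg`` is the
    visual angle of the fovea center relative to the scan center, so (0, 0)
    encodes central fixation and magnitude 1.5 the para-central calibration
    condition.
    """

    corneal_retardance_deg: float = 45.0
    corneal_axis_deg: float = 30.0
    henle_retardance_deg: float = 3.0
    fundus_reflectance: float = 1.0
    depolarized_fraction: float = 0.3
    fixation_offset_deg: tuple[float, float] = (0.0, 0.0)
    fixed_wp: Retarder | None = None
    henle_slow_axis_radial: bool = True

    def __post_init__(self) -> None:
        for name in ("fundus_reflectance", "depolarized_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        object.__setattr__(
            self, "fixation_offset_deg", tuple(float(x) for x in self.fixation_offset_deg)
        )


def rotator_matrix(angle_deg) -> np.ndarray:
    """Mueller matrix rotating the Stokes coordinate frame by ``angle_deg``.

    Accepts a scalar (returns 4x4) or an array of angles (returns (..., 4, 4)).
    Satisfies rotator(a) @ rotator(b) == rotator(a + b) and period 180 deg.
    """
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(2 * a), np.sin(2 * a)
    M = np.zeros(a.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 3, 3] = 1.0
    M[..., 1, 1] = c
    M[..., 1, 2] = s
    M[..., 2, 1] = -s
    M[..., 2, 2] = c
    return M


def _canonical_retarder(retardance_deg) -> np.ndarray:
    d = np.deg2rad(np.asarray(retardance_deg, dtype=float))
    c, s = np.cos(d), np.sin(d)
    M = np.zeros(d.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = 1.0
    M[..., 2, 2] = c
    M[..., 2, 3] = s
    M[..., 3, 2] = -s
    M[..., 3, 3] = c
    return M


def retarder_matrix(r: Retarder) -> np.ndarray:
    """Mueller matrix of a linear retarder (rotate in, retard, rotate out)."""
    return _retarder_matrix(r.retardance_deg, r.axis_deg)


def _retarder_matrix(retardance_deg, axis_deg) -> np.ndarray:
    axis = np.asarray(axis_deg, dtype=float)
    return (
        rotator_matrix(-axis)
        @ _canonical_retarder(retardance_deg)
        @ rotator_matrix(axis)
    )


def henle_axis(scan_angle_deg, offset_deg: Sequence[float], radius_deg: float):
    """Azimuth of the radial Henle-fiber direction at the scanned point.

    The scanned point sits at ``radius * (cos phi, sin phi)`` relative to the
    scan center; the fovea center sits at ``offset``. The fiber direction is
    the ray from the fovea center to the scanned point. Vectorized over
    ``scan_angle_deg``.
    """
    phi = np.deg2rad(np.asarray(scan_angle_deg, dtype=float))
    ox, oy = float(offset_deg[0]), float(offset_deg[1])
    dx = radius_deg * np.cos(phi) - ox
    dy = radius_deg * np.sin(phi) - oy
    if np.any(np.hypot(dx, dy) < 1e-9 * max(radius_deg, 1.0)):
        raise InvalidGeometryError("scanned point coincides with the fovea center")
    return np.rad2deg(np.arctan2(dy, dx))


def _round_trip_stokes(
    scan_angle_deg, eye: EyeOptics, cfg: ScanConfig, hwp_phase_deg: float = 0.0
) -> np.ndarray:
    """Stokes vectors of the polarized return for each scan angle.

    Output is normalized to unit launched intensity and excludes the
    reflectance/depolarization factors, which are applied by the callers.
    """
    phi = np.atleast_1d(np.asarray(scan_angle_deg, dtype=float))
    psi = cfg.hwp_ratio * phi + hwp_phase_deg

    # Henle geometry. Where the scanned point falls on the fovea center
    # itself (possible when the fixation offset reaches the scan circle, as
    # in the para-central calibration condition) there is no preferred fiber
    # direction and the local retardance vanishes, so those samples get zero
    # retardance instead of an error.
    rad = np.deg2rad(phi)
    ox, oy = eye.fixation_offset_deg
    dx = cfg.scan_radius_deg * np.cos(rad) - ox
    dy = cfg.scan_radius_deg * np.sin(rad) - oy
    dist = np.hypot(dx, dy)
    degenerate = dist < 1e-9 * max(cfg.scan_radius_deg, 1.0)
    axis = np.rad2deg(np.arctan2(dy, dx))
    if eye.henle_slow_axis_radial:
        axis = axis + 90.0  # fast axis tangential
    henle_ret = np.where(degenerate, 0.0, eye.henle_retardance_deg)

    S = np.broadcast_to(np.array([1.0, 1.0, 0.0, 0.0]), phi.shape + (4,)).copy()

    hwp = _retarder_matrix(180.0, psi)
    cornea = _retarder_matrix(eye.corneal_retardance_deg, eye.corneal_axis_deg)
    henle = _retarder_matrix(henle_ret, axis)
    wp = retarder_matrix(eye.fixed_wp) if eye.fixed_wp is not None else None

    def apply(M, S):
        if M.ndim == 2:
            return np.einsum("ij,nj->ni", M, S)
        return np.einsum("nij,nj->ni", M, S)

    # out: HWP -> (WP) -> cornea -> Henle; fundus reflection = identity;
    # back: Henle -> cornea -> (WP) -> HWP (same folded frame).
    S = apply(hwp, S)
    if wp is not None:
        S = apply(wp, S)
    S = apply(cornea, S)
    S = apply(henle, S)
    S = apply(henle, S)
    S = apply(cornea, S)
    if wp is not None:
        S = apply(wp, S)
    S = apply(hwp, S)
    return S


def detector_signal(
    scan_angle_deg, eye: EyeOptics, cfg: ScanConfig, hwp_phase_deg: float = 0.0
) -> np.ndarray:
    """Vectorized detector intensity over an array of scan angles.

    The polarizing beam splitter sends the component orthogonal to the
    launched horizontal polarization, (s0 - s1)/2, to the detector; the
    depolarized return contributes half its intensity, independent of the
    HWP angle.
    """
    R = eye.fundus_reflectance
    if R == 0.0:
        return np.zeros(np.shape(np.atleast_1d(scan_angle_deg)))
    S = _round_trip_stokes(scan_angle_deg, eye, cfg, hwp_phase_deg)
    polarized = R * (1.0 - eye.depolarized_fraction) * (S[:, 0] - S[:, 1]) / 2.0
    depol = R * eye.depolarized_fraction * 0.5
    return polarized + depol


def detector_sample(
    scan_angle_deg: float, eye: EyeOptics, cfg: ScanConfig, hwp_phase_deg: float = 0.0
) -> float:
    """Detector intensity for a single sample (scalar convenience wrapper)."""
    return float(detector_signal([scan_angle_deg], eye, cfg, hwp_phase_deg)[0])


def energy_budget(
    scan_angle_deg, eye: EyeOptics, cfg: ScanConfig, hwp_phase_deg: float = 0.0
):
    """Per-sample (transmitted, rejected, depolarized) intensity partition.

    ``transmitted`` is the unchanged component returned toward the source by
    the beam splitter, ``rejected`` the detected component; the three terms
    sum to the reflected intensity at every sample.
    """
    R = eye.fundus_reflectance
    S = _round_trip_stokes(scan_angle_deg, eye, cfg, hwp_phase_deg)
    pol = R * (1.0 - eye.depolarized_fraction)
    transmitted = pol * (S[:, 0] + S[:, 1]) / 2.0
    rejected = pol * (S[:, 0] - S[:, 1]) / 2.0
    depol = np.full_like(transmitted, R * eye.depolarized_fraction)
    return transmitted, rejected, depol
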