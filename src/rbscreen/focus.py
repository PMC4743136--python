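"""Differential focus detection on the bull's-eye photodetector.

Good focus concentrates the returning light on the center element; blur
spills it onto the annulus. The per-eye, per-record statistic is
(C - A)/(C + A) on the 4.5 f_s carrier powers of the two elements, passed
at >= 0.65 (the printed threshold is itself a passing level, unlike the
strict inequality of the fixation criterion), with the same 2-of-12
session rule as central fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CARRIER_HARMONIC, DegenerateRecordError, ScanConfig
from .phss import phss
from .polarization import EyeOptics
from .spectral import half_harmonic_powers
from .synthesis import (
    DEFAULT_BLUR_SCALE_D,
    FocusState,
    NoiseSpec,
    synthesize_record,
)

__all__ = [
    "FocusFeatures",
    "FocusCurve",
    "FD_THRESHOLD",
    "focus_goodness",
    "focus_features",
    "focus_decision",
    "focus_curve",
    "dioptric_conjugate",
]

FD_THRESHOLD = 0.65


@dataclass(frozen=True)
class FocusFeatures:
    """Carrier (4.5 f_s) powers of center (C) and annulus (A) for one eye."""

    C: float
    A: float
    eye: str = ""
    record: int = -1

    @property
    def goodness(self) -> float:
        return focus_goodness(self.C, self.A)


def focus_goodness(C: float, A: float) -> float:
    """Normalized goodness-of-focus statistic (C - A)/(C + A) in [-1, 1]."""
    if C < 0 or A < 0:
        raise ValueError("powers must be non-negative")
    if C + A == 0:
        raise DegenerateRecordError("no carrier power on either detector element")
    return (C - A) / (C + A)


def focus_features(p, cfg: ScanConfig | None = None) -> dict[str, FocusFeatures]:
    """Per-eye center/annulus carrier powers from a PhSS record."""
    cfg = cfg or p.cfg
    record = p.meta.get("record", -1) if getattr(p, "meta", None) else -1
    out = {}
    for eye, (ci, ai) in {"L": (0, 1), "R": (2, 3)}.items():
        C = half_harmonic_powers(p.samples[ci], cfg, harmonics=(CARRIER_HARMONIC,))
        A = half_harmonic_powers(p.samples[ai], cfg, harmonics=(CARRIER_HARMONIC,))
        out[eye] = FocusFeatures(C=C[CARRIER_HARMONIC], A=A[CARRIER_HARMONIC],
                                 eye=eye, record=record)
    return out


def focus_decision(goodness_values, threshold: float = FD_THRESHOLD, k: int = 2,
                   n: int = 12) -> bool:
    """Session-level focus rule: pass iff >= k of n records reach threshold.

    The boundary passes (goodness == threshold is a pass).
    """
    vals = list(goodness_values)
    if len(vals) != n:
        raise ValueError(f"expected {n} goodness values, got {len(vals)}")
    return sum(v >= threshold for v in vals) >= k


@dataclass
class FocusCurve:
    """Focus statistic vs added trial-lens power for one eye."""

    lens_powers_D: np.ndarray
    goodness: np.ndarray
    mode: str  # "cyclopleged" | "natural"
    peak_lens_D: float = field(init=False)
    crossing_lens_D: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.lens_powers_D = np.asarray(self.lens_powers_D, dtype=float)
        self.goodness = np.asarray(self.goodness, dtype=float)
        if self.lens_powers_D.shape != self.goodness.shape:
            raise ValueError("lens grid and goodness must have equal lengths")
        i = int(np.argmax(self.goodness))
        self.peak_lens_D = float(self.lens_powers_D[i])
        self.crossing_lens_D = self._crossing(i)

    def _crossing(self, peak_idx: int, level: float = FD_THRESHOLD) -> float | None:
        """Plus-side crossing of the pass level, linearly interpolated."""
        L, g = self.lens_powers_D[peak_idx:], self.goodness[peak_idx:]
        for j in range(len(g) - 1):
            if g[j] >= level > g[j + 1]:
                t = (g[j] - level) / (g[j] - g[j + 1])
                return float(L[j] + t * (L[j + 1] - L[j]))
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lens_power_D": self.lens_powers_D,
                             "goodness": self.goodness, "mode": self.mode})


def focus_curve(
    template: FocusState,
    lens_powers_D,
    eye: EyeOptics | None = None,
    cfg: ScanConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    blur_scale_D: float = DEFAULT_BLUR_SCALE_D,
) -> FocusCurve:
    """Sweep trial lenses in front of a simulated eye and record the statistic.

    Each lens power is run through the full pipeline: effective defocus ->
    center/annulus split -> record synthesis -> PhSS -> carrier powers ->
    (C - A)/(C + A). The curve reports its peak and the plus-side crossing
    of the pass threshold.
    """
    lens = np.asarray(lens_powers_D, dtype=float)
    if lens.size < 2:
        raise ValueError("need at least 2 lens powers")
    eye = eye or EyeOptics()
    cfg = cfg or ScanConfig()
    vals = []
    from dataclasses import replace

    for i, lp in enumerate(lens):
        fstate = replace(template, lens_power_D=float(lp))
        rec = synthesize_record((eye, eye), (fstate, fstate), noise=noise, cfg=cfg,
                                seed=seed + i, blur_scale_D=blur_scale_D)
        vals.append(focus_features(phss(rec), cfg)["L"].goodness)
    return FocusCurve(lens_powers_D=lens, goodness=np.array(vals),
                      mode="cyclopleged" if template.cyclopleged else "natural")


def dioptric_conjugate(distance_cm: float, delta_D: float) -> float:
    """Distance whose vergence is ``delta_D`` less than that of ``distance_cm``.

    E.g. the scanning-laser image is placed 0.75 D farther than the 33.3 cm
    accommodative target to offset the eye's longitudinal chromatic
    aberration: (33.3, 0.75) -> 44.4 cm.
    """
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    v = 100.0 / distance_cm - delta_D
    if v <= 0:
        raise ValueError("conjugate lies at or beyond infinity")
    return 100.0 / v
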