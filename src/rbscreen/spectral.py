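"""Synchronized-sampling power spectra and half-harmonic feature extraction.

Because the ADC is paced by the same clock that steps the scan, all
characteristic frequencies (2.5 ... 6.5 x f_s = 75 ... 195 Hz at the
defaults) fall on exact 1 Hz DFT bins of a 1-second record and need no
window. Powers are one-sided: P(f) = 2 |X_k|^2 / N^2 for interior bins
(|X_0|^2 / N^2 at DC), so the bin powers of a real signal sum to its mean
square (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import (
    CARRIER_HARMONIC,
    ConfigurationError,
    DegenerateRecordError,
    HALF_HARMONICS,
    ScanConfig,
)

__all__ = [
    "PowerFeatures",
    "NormalizedFeatures",
    "power_spectrum",
    "half_harmonic_powers",
    "extract_features",
    "normalize",
    "features_to_frame",
]

#: Relative floor under which the carrier power marks a record unusable.
P45_FLOOR = 1e-12


@dataclass(frozen=True)
class PowerFeatures:
    """The five half-harmonic spectral powers for one eye of one record."""

    P2_5: float
    P3_5: float
    P4_5: float
    P5_5: float
    P6_5: float
    eye: str = ""
    record: int = -1

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NormalizedFeatures:
    """Half-harmonic powers normalized by the gaze-independent carrier P4.5."""

    r_cf: float      # (P2.5 + P6.5) / P4.5
    r_para: float    # (P3.5 + P5.5) / P4.5
    r25: float
    r65: float
    r35: float
    r55: float
    eye: str = ""
    record: int = -1

    def as_dict(self) -> dict:
        return asdict(self)


def power_spectrum(samples, rate: float):
    """One-sided discrete power spectrum of a real signal.

    Returns ``(freqs, powers)``; no window is applied, as synchronized
    sampling makes the target frequencies leakage-free.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    P = np.abs(X) ** 2 / n**2
    scale = np.full(P.shape[-1], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    P = P * scale
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, P


def half_harmonic_powers(
    samples, cfg: ScanConfig, harmonics=HALF_HARMONICS, band: int = 0
) -> dict[float, float]:
    """Powers at the given half-integer harmonics of the scan frequency.

    ``band=0`` reads the single exact bin (default under synchronized
    sampling); ``band=b`` sums the +-b neighboring bins for jittered-rate
    emulation.
    """
    _, P = power_spectrum(samples, cfg.pacing_rate)
    out = {}
    for h in harmonics:
        k = cfg.harmonic_bin(h)
        if k >= P.shape[-1]:
            raise ConfigurationError(f"harmonic {h} f_s beyond Nyquist")
        out[h] = float(P[..., max(k - band, 0) : k + band + 1].sum(axis=-1))
    return out


def _eye_channels(samples: np.ndarray, eye: str) -> tuple[np.ndarray, np.ndarray]:
    idx = {"L": (0, 1), "R": (2, 3)}[eye]
    return samples[idx[0]], samples[idx[1]]


def extract_features(
    p, cfg: ScanConfig | None = None, channel_mode: str = "sum", band: int = 0
) -> dict[str, PowerFeatures]:
    """Half-harmonic powers per eye from a PhSS record.

    ``channel_mode='sum'`` (default) sums the center and annulus channels --
    the total collected light, robust to defocus; ``'center'`` uses the
    center channel only. Returns ``{'L': PowerFeatures, 'R': PowerFeatures}``.
    """
    cfg = cfg or p.cfg
    record = p.meta.get("record", -1) if getattr(p, "meta", None) else -1
    out = {}
    for eye in ("L", "R"):
        center, annulus = _eye_channels(p.samples, eye)
        if channel_mode == "sum":
            x = center + annulus
        elif channel_mode == "center":
            x = center
        else:
            raise ValueError(f"unknown channel_mode {channel_mode!r}")
        pw = half_harmonic_powers(x, cfg, band=band)
        out[eye] = PowerFeatures(
            P2_5=pw[2.5], P3_5=pw[3.5], P4_5=pw[4.5], P5_5=pw[5.5], P6_5=pw[6.5],
            eye=eye, record=record,
        )
    return out


def normalize(f: PowerFeatures) -> NormalizedFeatures:
    """Normalize the four fixation-dependent powers by the carrier P4.5.

    Raises :class:`DegenerateRecordError` when the carrier is absent (below
    ``P45_FLOOR`` of the total half-harmonic power): such a record carries no
    signal and must be excluded rather than classified.
    """
    total = f.P2_5 + f.P3_5 + f.P4_5 + f.P5_5 + f.P6_5
    if f.P4_5 <= 0 or (total > 0 and f.P4_5 < P45_FLOOR * total):
        raise DegenerateRecordError("carrier power P4.5 is zero or negligible")
    return NormalizedFeatures(
        r_cf=(f.P2_5 + f.P6_5) / f.P4_5,
        r_para=(f.P3_5 + f.P5_5) / f.P4_5,
        r25=f.P2_5 / f.P4_5,
        r65=f.P6_5 / f.P4_5,
        r35=f.P3_5 / f.P4_5,
        r55=f.P5_5 / f.P4_5,
        eye=f.eye,
        record=f.record,
    )


ALL_HALF_HARMONICS = tuple(k + 0.5 for k in range(9))
"""Half-integer harmonics up to 8.5 x f_s, for signature analysis."""

SIDEBAND_PAIRS = {"central": (2.5, 6.5), "paracentral": (3.5, 5.5)}
"""The fixation-dependent +-2 f_s and +-1 f_s sideband pairs of the carrier."""


def identify_carrier(powers_a: dict[float, float], powers_b: dict[float, float],
                     rel_tol: float = 0.2) -> float:
    """Harmonic of the largest spectral line insensitive to the gaze change.

    Given half-harmonic power dictionaries measured at two fixation offsets,
    returns the harmonic with the largest guaranteed power among those whose
    power changes by less than ``rel_tol`` (relative to the pair sum) between
    the offsets. This is the spin-generated carrier.
    """
    cand = [
        h for h in powers_a
        if abs(powers_a[h] - powers_b[h]) < rel_tol * (powers_a[h] + powers_b[h] + 1e-300)
    ]
    if not cand:
        raise ValueError("no offset-insensitive spectral line found")
    return max(cand, key=lambda h: min(powers_a[h], powers_b[h]))


def dominant_sideband_pair(powers: dict[float, float],
                           carrier: float = CARRIER_HARMONIC) -> tuple[float, float]:
    """The sideband pair carrying the predominant non-carrier power.

    The fixation-dependent power appears as a +-1 or +-2 f_s sideband pair
    around the carrier; this ranks the two candidate pairs by their summed
    power and returns the winner (lower harmonic first).
    """
    best = max(
        SIDEBAND_PAIRS.values(),
        key=lambda pair: sum(powers[h] for h in pair if h != carrier),
    )
    return best


FEATURE_COLUMNS = [
    "subject", "record", "eye", "label",
    "P2_5", "P3_5", "P4_5", "P5_5", "P6_5",
    "r_cf", "r_para", "r25", "r65", "r35", "r55",
]


def features_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble labeled feature rows into the canonical feature table."""
    df = pd.DataFrame(rows)
    return df[[c for c in FEATURE_COLUMNS if c in df.columns]]
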