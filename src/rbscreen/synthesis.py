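"""Synthetic four-channel records emulating the instrument's acquisition.

A record is 1 s of four photodetector channels (left/right eye x
center/annulus of the bull's-eye detector) sampled at 6000 S/s, 200 samples
per scan revolution. On top of the Mueller-model polarization signal the
generator adds the three noise classes the instrument sees:

* scan-synchronous background (depolarized light from skin and sclera) --
  exactly periodic over one revolution by construction,
* power-line interference at 60 Hz (two full cycles per revolution),
* white detector/amplifier noise.

Defocus moves a fraction of the returning light from the center to the
annulus of the bull's-eye detector; accommodation is emulated well enough
to reproduce the worked trial-lens arithmetic of cyclopleged vs natural
focus curves.

The 4-stage programmable-gain front end of the real instrument gives the
strong 4.5 f_s carrier less gain than the fixation sidebands to avoid
saturating the analog chain; :data:`DEFAULT_GAIN_TABLE` emulates that with
a 1/8 relative gain at 4.5 f_s, which also places the normalized features
on the scale spanned by the decision-threshold grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScanConfig
from .phss import phss
from .polarization import EyeOptics, detector_signal
from .spectral import extract_features, features_to_frame, normalize

__all__ = [
    "NoiseSpec",
    "FocusState",
    "RawRecord",
    "DEFAULT_GAIN_TABLE",
    "DEFAULT_BLUR_SCALE_D",
    "DILATED_BLUR_FACTOR",
    "annulus_fraction_at_goodness",
    "effective_defocus",
    "defocus_split",
    "synthesize_record",
    "random_eye",
    "make_calibration_set",
    "write_record",
    "read_record",
]

CHANNELS = ("ch_LC", "ch_LA", "ch_RC", "ch_RA")

#: Per-harmonic relative gain of the emulated analog front end (flat = {}).
DEFAULT_GAIN_TABLE: dict[float, float] = {4.5: 0.125}

#: Pupil-dilation steepening of the blur model under cycloplegic drops.
DILATED_BLUR_FACTOR = 0.5


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes of the three simulated noise classes (arbitrary units)."""

    background_amp: float = 0.5
    background_harmonics: int = 5
    line_amp: float = 0.2
    white_sigma: float = 0.02

    def __post_init__(self) -> None:
        if min(self.background_amp, self.line_amp, self.white_sigma) < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class FocusState:
    """Dioptric state of one eye in front of the instrument.

    All quantities in diopters. ``stimulus_vergence_D`` is the vergence of
    the accommodative target (3.0 D at the 33.3 cm testing distance);
    ``refraction_D`` the cycloplegic refraction relative to infinity
    (positive = hyperopic); ``lens_power_D`` a trial lens added in front of
    the eye. ``tonic_D`` is habitual accommodative tone that the subject
    cannot relax; ``accommodation_lag`` is the fraction of the remaining
    accommodative demand left uncorrected (a typical near-work accommodative
    lag), which makes natural-mode focus curves fall slowly but monotonically
    on the minus-lens side.
    """

    stimulus_vergence_D: float = 3.0
    lens_power_D: float = 0.0
    refraction_D: float = 0.0
    tonic_D: float = 0.0
    cyclopleged: bool = False
    accommodation_amplitude_D: float = 12.0
    accommodation_lag: float = 0.3


def effective_defocus(f: FocusState) -> float:
    """Dioptric distance of the retinal conjugate from the target.

    Accommodative demand = stimulus vergence + refraction - trial lens.
    A cyclopleged eye cannot respond at all; a natural eye responds with the
    demand clipped between its tonic floor and its amplitude, less a small
    lag. Zero means best focus.
    """
    demand = f.stimulus_vergence_D + f.refraction_D - f.lens_power_D
    if f.cyclopleged:
        response = 0.0
    else:
        clipped = min(max(demand, f.tonic_D), f.accommodation_amplitude_D)
        response = f.tonic_D + (1.0 - f.accommodation_lag) * (clipped - f.tonic_D)
    return demand - response


def annulus_fraction_at_goodness(g: float) -> float:
    """Annulus amplitude fraction at which the focus statistic equals ``g``.

    Channel amplitudes split (1-f)/f, so the spectral powers entering
    (C-A)/(C+A) split quadratically and the statistic is
    (1-2f)/(1-2f+2f^2); this inverts it on f in [0, 1/2).
    """
    if not -1.0 < g <= 1.0:
        raise ValueError("goodness must be in (-1, 1]")
    if g == 1.0:
        return 0.0
    return (-(1.0 - g) + math.sqrt((1.0 - g) * (1.0 + g))) / (2.0 * g)


#: Blur scale (D) such that the pipeline focus statistic crosses its 0.65
#: pass threshold at 1.0 D of defocus with an average (undilated) pupil.
DEFAULT_BLUR_SCALE_D = 1.0 / math.sqrt(-math.log(1.0 - annulus_fraction_at_goodness(0.65)))


def defocus_split(d: float, blur_scale_D: float = DEFAULT_BLUR_SCALE_D) -> float:
    """Fraction of returning light spilling onto the annulus at defocus ``d``.

    Even, saturating in |d|, ~0 at best focus: 1 - exp(-(d/blur_scale)^2).
    """
    if blur_scale_D <= 0:
        raise ValueError("blur_scale_D must be positive")
    return 1.0 - math.exp(-((d / blur_scale_D) ** 2))


@dataclass
class RawRecord:
    """One 1-second, four-channel sample block plus generation metadata."""

    samples: np.ndarray  # (4, N): LC, LA, RC, RA
    cfg: ScanConfig
    meta: dict = field(default_factory=dict)


def _noise_channel(rng: np.random.Generator, noise: NoiseSpec, cfg: ScanConfig) -> np.ndarray:
    n = cfg.samples_per_record
    spr = cfg.steps_per_rev
    out = np.zeros(n)
    if noise.background_amp > 0 and noise.background_harmonics > 0:
        k = np.arange(spr)
        profile = np.zeros(spr)
        for h in range(1, noise.background_harmonics + 1):
            a = noise.background_amp * rng.uniform(0.3, 1.0) / h
            ph = rng.uniform(0, 2 * np.pi)
            profile += a * np.cos(2 * np.pi * h * k / spr + ph)
        out += np.tile(profile, n // spr)
    if noise.line_amp > 0:
        t = np.arange(n) / cfg.pacing_rate
        out += noise.line_amp * np.sin(2 * np.pi * cfg.line_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.white_sigma > 0:
        out += rng.normal(0.0, noise.white_sigma, n)
    return out


def _apply_gain_table(x: np.ndarray, cfg: ScanConfig, gain_table: dict[float, float]) -> np.ndarray:
    """Emulate the analog filter as per-characteristic-frequency gain."""
    if not gain_table:
        return x
    X = np.fft.rfft(x, axis=-1)
    for harmonic, g in gain_table.items():
        X[..., cfg.harmonic_bin(harmonic)] *= g
    return np.fft.irfft(X, n=x.shape[-1], axis=-1)


def _blur_scale_for(focus: FocusState, blur_scale_D: float) -> float:
    return blur_scale_D * (DILATED_BLUR_FACTOR if focus.cyclopleged else 1.0)


def synthesize_record(
    eyes: tuple[EyeOptics, EyeOptics],
    focus: tuple[FocusState, FocusState] | None = None,
    noise: NoiseSpec | None = None,
    cfg: ScanConfig | None = None,
    seed: int = 0,
    gain_table: dict[float, float] | None = None,
    blur_scale_D: float = DEFAULT_BLUR_SCALE_D,
    meta: dict | None = None,
) -> RawRecord:
    """Simulate one four-channel record for a (left, right) pair of eyes.

    Deterministic for a fixed seed. The center channel carries
    ``(1 - f_A)`` of the polarization signal and the annulus ``f_A``, where
    ``f_A`` follows from the eye's effective defocus; each channel gets an
    independent noise draw, with the scan-synchronous background identical
    across the record's revolutions by construction.
    """
    cfg = cfg or ScanConfig()
    noise = noise if noise is not None else NoiseSpec()
    focus = focus or (FocusState(), FocusState())
    gain_table = DEFAULT_GAIN_TABLE if gain_table is None else gain_table
    rng = np.random.default_rng(seed)
    angles = cfg.scan_angles_deg()

    chans = []
    truth = {"fixation_offset": [], "defocus_D": [], "annulus_fraction": []}
    for eye, fstate in zip(eyes, focus):
        sig = detector_signal(angles, eye, cfg)
        d = effective_defocus(fstate)
        f_a = defocus_split(d, _blur_scale_for(fstate, blur_scale_D))
        truth["fixation_offset"].append(list(eye.fixation_offset_deg))
        truth["defocus_D"].append(d)
        truth["annulus_fraction"].append(f_a)
        center = (1.0 - f_a) * sig + _noise_channel(rng, noise, cfg)
        annulus = f_a * sig + _noise_channel(rng, noise, cfg)
        chans.extend([center, annulus])

    samples = _apply_gain_table(np.stack(chans), cfg, gain_table)
    m = {"seed": seed, "truth": truth}
    if meta:
        m.update(meta)
    return RawRecord(samples=samples, cfg=cfg, meta=m)


def random_eye(
    rng: np.random.Generator,
    fixation_offset_deg=(0.0, 0.0),
    henle_retardance_deg: float = 3.0,
    corneal_range=(20.0, 80.0),
) -> EyeOptics:
    """Draw an eye with random corneal birefringence.

    Corneal retardance uniform on [20, 80] deg and axis uniform on
    [0, 180) deg -- magnitudes chosen to give robust fixation sidebands
    across the simulated population.
    """
    return EyeOptics(
        corneal_retardance_deg=rng.uniform(*corneal_range),
        corneal_axis_deg=rng.uniform(0.0, 180.0),
        henle_retardance_deg=henle_retardance_deg,
        fixation_offset_deg=tuple(fixation_offset_deg),
    )


#: The four para-central gaze directions: 12, 3, 6 and 9 o'clock at 1.5 deg.
PARA_OFFSETS = {
    "12h": (0.0, 1.5),
    "3h": (1.5, 0.0),
    "6h": (0.0, -1.5),
    "9h": (-1.5, 0.0),
}


def make_calibration_set(
    n_subjects: int = 5,
    cfg: ScanConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    records_per_condition: int = 12,
    channel_mode: str = "sum",
    offset_deg: float = 1.5,
) -> pd.DataFrame:
    """Generate the labeled calibration feature table.

    Each subject contributes ``records_per_condition`` records x 2 eyes with
    the scan centered (label ``CF``) and the same number for each of the four
    para-central gaze directions at ``offset_deg`` (label ``paraCF``). At the
    defaults this reproduces the 120-"eye" CF set and 480-"eye" para-CF set
    structure of the calibration procedure.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    conditions = [("CF", (0.0, 0.0))] + [
        ("paraCF", (sx * offset_deg / 1.5, sy * offset_deg / 1.5))
        for sx, sy in PARA_OFFSETS.values()
    ]
    for subj in range(n_subjects):
        base = [random_eye(rng) for _ in range(2)]
        for label, off in conditions:
            eyes = tuple(
                EyeOptics(
                    corneal_retardance_deg=e.corneal_retardance_deg,
                    corneal_axis_deg=e.corneal_axis_deg,
                    henle_retardance_deg=e.henle_retardance_deg,
                    fixation_offset_deg=off,
                )
                for e in base
            )
            for rec in range(records_per_condition):
                record = synthesize_record(
                    eyes, noise=noise, cfg=cfg,
                    seed=int(rng.integers(0, 2**31)),
                    meta={"subject": subj, "record": rec},
                )
                feats = extract_features(phss(record), cfg, channel_mode=channel_mode)
                for eye_id, pf in feats.items():
                    nf = normalize(pf)
                    rows.append(
                        {"subject": subj, "record": rec, "eye": eye_id, "label": label}
                        | pf.as_dict() | nf.as_dict()
                    )
    df = features_to_frame(rows)
    return df.loc[:, ~df.columns.duplicated()]


# ---------------------------------------------------------------------------
# Record file round trip: CSV samples + JSON sidecar with config and truth.

def write_record(record: RawRecord, csv_path: str | Path) -> Path:
    """Write a record to CSV plus a ``.json`` sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {"sample_index": np.arange(record.samples.shape[1])}
        | {name: record.samples[i] for i, name in enumerate(CHANNELS)}
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"cfg": record.cfg.to_dict(), "meta": record.meta}, indent=1, sort_keys=True)
    )
    return csv_path


def read_record(csv_path: str | Path) -> RawRecord:
    """Read a record written by :func:`write_record`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    samples = np.stack([df[name].to_numpy(dtype=float) for name in CHANNELS])
    return RawRecord(samples=samples, cfg=ScanConfig.from_dict(side["cfg"]), meta=side["meta"])
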