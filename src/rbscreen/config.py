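"""Scan-geometry and timing constants shared by every stage.

The instrument steps a motor-driven circular scan at an exact multiple of the
power-line frequency and acquires one sample per motor step, so that each
1-second record contains an integer number of scan revolutions and every
characteristic frequency falls on an exact DFT bin.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ScanConfig:
    """Sampling and scan-rate constants.

    Attributes
    ----------
    pacing_rate : float
        Motor/ADC pacing in steps (= samples) per second. Default 6000,
        i.e. 100x the 60 Hz line frequency.
    steps_per_rev : int
        Motor steps per scan revolution (1.8 deg/step -> 200).
    hwp_ratio : float
        Spin rate of the half-wave plate as a fraction of the scan rate.
    scan_radius_deg : float
        Visual-angle radius of the scanning circle (3 deg diameter -> 1.5).
    line_freq : float
        Power-line frequency in Hz.
    record_seconds : float
        Duration of one record.
    """

    pacing_rate: float = 6000.0
    steps_per_rev: int = 200
    hwp_ratio: float = 9.0 / 16.0
    scan_radius_deg: float = 1.5
    line_freq: float = 60.0
    record_seconds: float = 1.0

    def __post_init__(self) -> None:
        if self.pacing_rate <= 0 or self.steps_per_rev <= 0:
            raise ValueError("pacing_rate and steps_per_rev must be positive")
        n = self.pacing_rate * self.record_seconds
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("record must contain an integer number of samples")
        if round(n) % self.steps_per_rev != 0:
            raise ConfigurationError(
                "record must contain an integer number of scan revolutions "
                f"({n} samples, {self.steps_per_rev} steps/rev)"
            )

    @property
    def scan_freq(self) -> float:
        """Scan rate f_s in revolutions per second (default 6000/200 = 30)."""
        return self.pacing_rate / self.steps_per_rev

    @property
    def samples_per_record(self) -> int:
        return round(self.pacing_rate * self.record_seconds)

    @property
    def revs_per_record(self) -> int:
        return self.samples_per_record // self.steps_per_rev

    def scan_angles_deg(self):
        import numpy as np

        k = np.arange(self.samples_per_record)
        return k * (360.0 / self.steps_per_rev)

    def harmonic_bin(self, harmonic: float) -> int:
        """DFT bin index of ``harmonic * f_s`` for a full record.

        Raises :class:`ConfigurationError` if the frequency does not fall on
        an exact bin (synchronized sampling guarantees it at the defaults).
        """
        f = harmonic * self.scan_freq
        b = f * self.record_seconds
        if abs(b - round(b)) > 1e-9:
            raise ConfigurationError(f"harmonic {harmonic} f_s is not bin-aligned")
        return round(b)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        return cls(**d)


class ConfigurationError(ValueError):
    """Record length / bin alignment inconsistent with the scan geometry."""


class InvalidGeometryError(ValueError):
    """Scanned retinal point coincides with the fovea center."""


class DegenerateRecordError(ValueError):
    """Record carries no usable carrier power; it cannot be classified."""


HALF_HARMONICS = (2.5, 3.5, 4.5, 5.5, 6.5)
"""Characteristic half-integer harmonics (x f_s) used by the decision logic."""

CARRIER_HARMONIC = 4.5
"""Spin-generated, gaze-independent carrier harmonic (x f_s)."""
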