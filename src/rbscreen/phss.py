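"""Phase-shift subtraction (PhSS).

Every noise source that repeats over one scan revolution -- depolarized
background from skin and sclera, and power-line interference (exactly two
60 Hz cycles per revolution at the default 30 rev/s) -- is cancelled by
subtracting each record from itself shifted by one scan period, while every
odd multiple of half the scan frequency is doubled in amplitude:
|1 - e^{-i 2 pi (k + 1/2)}| = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, ScanConfig

__all__ = ["PhssRecord", "phss", "phss_array"]


@dataclass
class PhssRecord:
    """Output of phase-shift subtraction: same channel layout as the input."""

    samples: np.ndarray  # (channels, N)
    cfg: ScanConfig
    shift_samples: int
    meta: dict | None = None


def phss_array(x: np.ndarray, shift: int, circular: bool = True) -> np.ndarray:
    """y[n] = x[n] - x[n - shift], along the last axis.

    Circular mode (default) wraps around the record, which is exact because a
    record holds an integer number of scan periods under synchronized
    sampling; truncated mode emulates a streaming subtraction and drops the
    first ``shift`` samples.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if circular:
        if n % shift != 0:
            raise ConfigurationError(
                f"record length {n} is not an integer number of scan periods ({shift})"
            )
        return x - np.roll(x, shift, axis=-1)
    return x[..., shift:] - x[..., :-shift]


def phss(record, circular: bool = True) -> PhssRecord:
    """Apply phase-shift subtraction to a raw record (all channels)."""
    cfg: ScanConfig = record.cfg
    shift = cfg.steps_per_rev
    out = phss_array(record.samples, shift, circular=circular)
    meta = dict(record.meta) if getattr(record, "meta", None) else None
    return PhssRecord(samples=out, cfg=cfg, shift_samples=shift, meta=meta)
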