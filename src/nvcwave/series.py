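"""Evenly sampled time series — the carrier for EEG, envelopes, aEEG margins and SctO2."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["UniformSeries"]


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values. Stored as a read-only float64 array.
    rate : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Physical units carried as metadata (e.g. ``"uV"`` or ``"%"``).
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (n / rate)."""
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    def with_values(self, values: np.ndarray, units: str | None = None) -> "UniformSeries":
        """Copy of this series with new sample values (same rate and origin)."""
        return replace(self, values=np.asarray(values), units=self.units if units is None else units)

    def head(self, n: int) -> "UniformSeries":
        return replace(self, values=self.values[:n])
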