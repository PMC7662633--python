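"""Uniformly sampled 1-D signal container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like of float
        The signal values (e.g. µV for EEG). Must contain at least two
        finite samples.
    rate_hz : float
        Sampling rate in Hz; strictly positive.
    id : str, optional
        Free-form identifier (channel name, epoch index, ...).
    """

    samples: np.ndarray
    rate_hz: float
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 2:
            raise ValueError("a TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain NaN or infinite values")
        if not (np.isfinite(self.rate_hz) and self.rate_hz > 0):
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate_hz", float(self.rate_hz))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate_hz

    def with_samples(self, samples: np.ndarray, id: str | None = None) -> "TimeSeries":
        """A new series with the same rate (used for derived signals)."""
        return TimeSeries(samples, self.rate_hz, id if id is not None else self.id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return self.rate_hz == other.rate_hz and np.array_equal(
            self.samples, other.samples
        )
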