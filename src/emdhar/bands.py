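"""Conventional FFT band decomposition of EEG into brain-wave bands.

The baseline against which the EMD path is compared: the signal's FFT
coefficients outside a band are zeroed and the inverse transform taken.
Because this is a pure spectral mask it is linear-phase — a pass-band tone
comes back with no phase shift — unlike the IIR filters it replaces.

Nine conventional bands are extracted, three of them (low-β, whole-β)
overlapping views of the β range rather than a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from .signal import TimeSeries

__all__ = ["BandDefinition", "BandSet", "BAND_DEFINITIONS", "fft_bandpass", "extract_bands"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi}]")


#: The nine brain-wave bands, in fixed extraction order.  Upper edges of
#: SMR and mid-beta stop just short of the next band so the closed-interval
#: mask keeps the non-overlapping quintet disjoint at 0.01 Hz resolution;
#: low-beta and whole-beta deliberately overlap the SMR/beta range.
BAND_DEFINITIONS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("smr", 12.0, 14.99),
    BandDefinition("mid_beta", 15.0, 19.99),
    BandDefinition("high_beta", 20.0, 30.0),
    BandDefinition("low_beta", 12.0, 19.0),
    BandDefinition("whole_beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 49.0),
)

#: Overall EEG band of interest; also exported as the broadband reference.
BROADBAND = BandDefinition("broadband", 0.5, 49.0)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BAND_DEFINITIONS)


@dataclass(frozen=True)
class BandSet:
    """The nine band-limited signals, keyed by band name in fixed order."""

    bands: dict[str, TimeSeries]

    def __post_init__(self) -> None:
        if tuple(self.bands) != BAND_NAMES:
            raise ValueError(f"bands must be exactly {BAND_NAMES} in order")

    def __getitem__(self, name: str) -> TimeSeries:
        return self.bands[name]

    def __iter__(self):
        return iter(self.bands.items())


def fft_bandpass(s: TimeSeries, f_lo: float, f_hi: float) -> TimeSeries:
    """Band-limit a signal by zeroing FFT bins outside [f_lo, f_hi].

    The interval is closed: a bin sitting exactly on an edge is kept.  The
    real-input FFT is used, so the conjugate-symmetric negative-frequency
    half is masked implicitly and the output is exactly real.
    """
    if f_lo >= f_hi:
        raise ValueError(f"invalid band: f_lo={f_lo} >= f_hi={f_hi}")
    nyquist = s.rate_hz / 2
    if f_hi > nyquist:
        raise ValueError(f"f_hi={f_hi} exceeds Nyquist frequency {nyquist}")
    x = s.samples
    coef = rfft(x)
    f = rfftfreq(x.size, d=1.0 / s.rate_hz)
    coef[(f < f_lo) | (f > f_hi)] = 0.0
    return s.with_samples(irfft(coef, n=x.size))


def extract_bands(s: TimeSeries) -> BandSet:
    """Decompose a signal into the nine conventional brain-wave bands.

    Requires a sampling rate of at least 98 Hz so the 49 Hz gamma edge is
    below Nyquist.
    """
    if s.rate_hz < 98:
        raise ValueError(
            f"rate {s.rate_hz} Hz too low: gamma extends to 49 Hz, need >= 98 Hz"
        )
    return BandSet(
        bands={
            b.name: fft_bandpass(s, b.f_lo, b.f_hi) for b in BAND_DEFINITIONS
        }
    )
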