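"""Band separation and envelope detection.

Wall movements of the fetal heart occupy roughly 100-300 Hz of the
demodulated Doppler signal and valve movements 300-600 Hz; band-pass
filtering separates them.  The signal is then reduced to a non-negative
envelope, either by full-wave rectification followed by low-pass
filtering, or by the magnitude of the analytic (Hilbert) signal with
optional moving-average smoothing.  All filters are 4th-order
Butterworth applied forward-backward, so beat timing is not skewed by
filter group delay.  Envelopes are resampled to a fixed 1 kHz rate: the
autocorrelation lag quantum downstream is then exactly 1 ms.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

from .simulate import UltrasoundRecord

__all__ = [
    "BandSpec",
    "Envelope",
    "WALL_BAND",
    "VALVE_BAND",
    "FULL_BAND",
    "ENVELOPE_RATE",
    "bandpass",
    "envelope_rectify_lowpass",
    "envelope_hilbert",
]

ENVELOPE_RATE = 1000.0  # [Hz]

#: allowed low-pass cutoffs for the rectify+LPF envelope [Hz]
RECTIFY_CUTOFFS = (None, 25.0, 50.0, 75.0, 100.0, 150.0)
#: allowed moving-average lengths for the Hilbert envelope [raw samples]
HILBERT_MA_LENGTHS = (None, 11, 21)


@dataclass(frozen=True)
class BandSpec:
    """Band-pass corner frequencies [Hz]."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError("need 0 < low < high")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2.0:
            raise ValueError(f"band ({self.low}, {self.high}) infeasible for fs={fs}")


WALL_BAND = BandSpec(100.0, 300.0)
VALVE_BAND = BandSpec(300.0, 600.0)
FULL_BAND = BandSpec(100.0, 600.0)


@dataclass
class Envelope:
    """Non-negative unipolar envelope at the fixed 1 kHz envelope rate.

    ``t0`` is the alignment offset [ms] of the first sample relative to
    the source record (zero for all paths in this module).
    """

    values: np.ndarray
    rate: float = ENVELOPE_RATE
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times [ms]."""
        return self.t0 + np.arange(len(self.values)) * 1000.0 / self.rate


def bandpass(record: UltrasoundRecord, band: BandSpec) -> UltrasoundRecord:
    """Zero-phase 4th-order Butterworth band-pass, same length as input."""
    band.validate_for(record.fs)
    sos = butter(4, [band.low, band.high], btype="bandpass", fs=record.fs, output="sos")
    return UltrasoundRecord(sosfiltfilt(sos, record.samples), record.fs)


def _resample_to_envelope_rate(x: np.ndarray, fs: float) -> np.ndarray:
    if fs == ENVELOPE_RATE:
        return x
    frac = Fraction(ENVELOPE_RATE / fs).limit_denominator(1000)
    return resample_poly(x, frac.numerator, frac.denominator)


def envelope_rectify_lowpass(record: UltrasoundRecord, cutoff: float | None = 50.0) -> Envelope:
    """Full-wave rectification, zero-phase low-pass, resample to 1 kHz.

    ``cutoff`` of ``None`` skips the low-pass stage (rectification only).
    Tiny negative undershoot from filtering/resampling is clipped to 0:
    an envelope is a magnitude by definition.
    """
    if cutoff not in RECTIFY_CUTOFFS:
        raise ValueError(f"cutoff must be one of {RECTIFY_CUTOFFS}")
    x = np.abs(record.samples)
    if cutoff is not None:
        sos = butter(4, cutoff, btype="lowpass", fs=record.fs, output="sos")
        x = sosfiltfilt(sos, x)
    x = _resample_to_envelope_rate(x, record.fs)
    return Envelope(np.maximum(x, 0.0))


def envelope_hilbert(record: UltrasoundRecord, ma_len: int | None = 21) -> Envelope:
    """Analytic-signal magnitude, optional centered moving average, resample to 1 kHz.

    The moving-average length is counted in raw signal samples and is
    applied before resampling.
    """
    if ma_len not in HILBERT_MA_LENGTHS:
        raise ValueError(f"ma_len must be one of {HILBERT_MA_LENGTHS}")
    x = np.abs(hilbert(record.samples))
    if ma_len is not None:
        kernel = np.ones(ma_len) / ma_len
        x = np.convolve(x, kernel, mode="same")
    x = _resample_to_envelope_rate(x, record.fs)
    return Envelope(np.maximum(x, 0.0))
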