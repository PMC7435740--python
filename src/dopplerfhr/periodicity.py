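"""Instantaneous periodicity measurement on the envelope.

A sliding window of width D over the 1 kHz envelope yields, every K ms,
one normalized autocorrelation curve; the lag of its dominant peak in
the physiological range is the instantaneous period estimate F_j [ms].
Two safeguards handle poor signal quality:

* if the peak amplitude is below ``p_th`` (0.1) the measurement is a
  loss marker;
* if it is below the prediction gate (0.5) a trapezoidal *prediction
  function* centred on the last reliable period re-weights the curve
  before the argmax, suppressing spurious peaks far from the expected
  period.  A period found this way is flagged ``predicted`` and does not
  move the prediction centre for later windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .preprocessing import Envelope

__all__ = [
    "AfConfig",
    "AFCurve",
    "InstantMeasurement",
    "autocorrelation",
    "trapezoidal_pf",
    "measure_instantaneous",
]

AF_WINDOW_WIDTHS = (0.8, 1.0, 1.5, 2.0, 3.0)   # [s]
AF_STEPS = (25.0, 250.0)                       # [ms]
PF_WIDTHS = (125.0, 250.0, 500.0)              # lower-base S [ms]


@dataclass(frozen=True)
class AfConfig:
    """Autocorrelation / prediction configuration.

    D [s] window width; K [ms] repetition step; ``lag_range`` [ms] the
    physiological period search range; ``p_th`` loss threshold on the AF
    peak; ``pf_gate`` the amplitude below which prediction kicks in;
    S [ms] the trapezoid's lower-base width.  The searchable lag is
    additionally capped at D*1000 - 200 ms so every candidate lag keeps
    at least 200 ms of overlap support inside the window.
    """

    D: float = 1.0
    K: float = 25.0
    lag_range: tuple = (250.0, 1000.0)
    p_th: float = 0.1
    pf_enabled: bool = True
    S: float = 500.0
    pf_gate: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.lag_range
        if not (0 < lo < hi):
            raise ValueError("invalid lag range")
        if not (0.0 < self.p_th < self.pf_gate < 1.0):
            raise ValueError("need 0 < p_th < pf_gate < 1")
        if self.D * 1000.0 < lo + 200.0:
            raise ValueError("window too short for the requested lag range")

    @property
    def effective_lag_range(self) -> tuple:
        lo, hi = self.lag_range
        return lo, min(hi, self.D * 1000.0 - 200.0)


@dataclass
class AFCurve:
    """Normalized autocorrelation over integer-ms lags (AF(0) = 1)."""

    lags: np.ndarray     # [ms]
    values: np.ndarray

    def argmax_in(self, lo: float, hi: float, tie_tol: float = 0.01) -> tuple:
        """(lag, value) of the dominant peak over [lo, hi].

        Among *local* maxima whose amplitude comes within ``tie_tol`` of
        the global maximum, the shortest lag wins: near-equal peaks at
        lag multiples are period ambiguities, and preferring the shorter
        lag avoids half-rate errors.
        """
        mask = (self.lags >= lo) & (self.lags <= hi)
        if not np.any(mask):
            raise ValueError("empty lag range")
        idx = np.nonzero(mask)[0]
        v = self.values
        best = idx[int(np.argmax(v[idx]))]
        interior = idx[(idx > 0) & (idx < len(v) - 1)]
        peaks = interior[(v[interior] >= v[interior - 1]) & (v[interior] >= v[interior + 1])]
        near = peaks[v[peaks] >= v[best] - tie_tol]
        if len(near):
            best = int(near[0])
        return float(self.lags[best]), float(self.values[best])


@dataclass
class InstantMeasurement:
    """One periodicity measurement F_j.

    ``t`` is the window-end timestamp [ms]; ``F`` the period [ms];
    ``af_peak`` the (pre-prediction) peak amplitude; ``predicted`` marks
    values obtained through the prediction function; ``valid`` is False
    for loss markers.
    """

    t: float
    F: float
    af_peak: float
    predicted: bool = False
    valid: bool = True


def autocorrelation(window: np.ndarray, max_lag: int) -> AFCurve | None:
    """Mean-removed autocorrelation with symmetric per-lag normalization.

    Each lag's product sum is divided by the mean energy of the two
    overlapping segments (the normalized square-difference convention of
    pitch trackers):

        af(k) = 2 * sum(x[i] x[i+k]) / sum(x[i]^2 + x[i+k]^2).

    The result is bounded by 1 at every lag (Cauchy-Schwarz), has
    af(0) = 1 exactly, carries no finite-window taper — so the absolute
    peak-amplitude thresholds for loss (0.1) and prediction (0.5) mean
    the same thing at every period — and cannot blow up at long lags.
    Returns None for an all-constant window (periodicity undefined; the
    caller emits a loss marker).
    """
    x = np.asarray(window, dtype=float)
    if np.ptp(x) == 0.0:
        return None
    x = x - x.mean()
    r0 = float(np.dot(x, x))
    n = len(x)
    if r0 <= n * (1e-12 * max(1.0, float(np.max(np.abs(window))))) ** 2:
        return None
    nfft = int(2 ** np.ceil(np.log2(n + max_lag + 1)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    s = np.cumsum(x * x)
    E = s[-1]
    k = np.arange(max_lag + 1)
    head = s[n - 1 - k]                      # energy of x[0 .. n-k-1]
    tail = E - np.concatenate([[0.0], s[: max_lag]])  # energy of x[k .. n-1]
    m = head + tail
    values = np.where(m > 0, 2.0 * r / np.maximum(m, 1e-300), 0.0)
    values[0] = 1.0
    return AFCurve(k.astype(float), values)


def trapezoidal_pf(af: AFCurve, center: float, S: float) -> AFCurve:
    """Multiply the AF by a trapezoidal window centred on the expected period.

    The upper base (plateau, weight 1) is S/4 wide; the lower base is S
    (weight reaches 0 at center +/- S/2); outside the lower base the
    weight is 0.  Pointwise multiplication by w <= 1 can only lower the
    curve.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    d = np.abs(af.lags - center)
    w = np.clip((S / 2.0 - d) / (S / 2.0 - S / 8.0), 0.0, 1.0)
    return AFCurve(af.lags, af.values * w)


def measure_instantaneous(
    env: Envelope, cfg: AfConfig = AfConfig(), start_ms: float = 0.0
) -> list:
    """Slide a D-wide window with hop K over the envelope and measure F_j.

    The first window starts at ``start_ms`` (the segmentation starting
    point P, when one is used).  Measurements are stamped at the window
    end.  The prediction centre is the last valid period that was *not*
    itself predicted.
    """
    n_win = int(round(cfg.D * 1000.0 * env.rate / 1000.0))
    hop = cfg.K * env.rate / 1000.0
    values = env.values
    if len(values) < n_win:
        import warnings

        warnings.warn("envelope shorter than the AF window; no measurements", stacklevel=2)
        return []
    lo, hi = cfg.effective_lag_range
    max_lag = int(round(hi))

    out: list = []
    pf_center: float | None = None
    k = 0
    while True:
        i0 = int(round((start_ms - env.t0) * env.rate / 1000.0 + k * hop))
        i1 = i0 + n_win
        if i0 < 0:
            k += 1
            continue
        if i1 > len(values):
            break
        t_end = env.t0 + i1 * 1000.0 / env.rate
        af = autocorrelation(values[i0:i1], max_lag)
        if af is None:
            out.append(InstantMeasurement(t_end, float("nan"), 0.0, predicted=False, valid=False))
            k += 1
            continue
        F, peak = af.argmax_in(lo, hi)
        predicted = False
        if peak < cfg.p_th:
            out.append(InstantMeasurement(t_end, float("nan"), peak, predicted=False, valid=False))
            k += 1
            continue
        if cfg.pf_enabled and peak < cfg.pf_gate and pf_center is not None:
            weighted = trapezoidal_pf(af, pf_center, cfg.S)
            F, _ = weighted.argmax_in(lo, hi)
            predicted = True
        out.append(InstantMeasurement(t_end, F, peak, predicted=predicted, valid=True))
        if not predicted:
            pf_center = F
        k += 1
    return out


def measurements_to_arrays(measurements: list) -> tuple:
    """(t, F, valid) arrays from a measurement list."""
    t = np.array([m.t for m in measurements], dtype=float)
    F = np.array([m.F for m in measurements], dtype=float)
    valid = np.array([m.valid for m in measurements], dtype=bool)
    return t, F, valid
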