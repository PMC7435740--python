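"""Method D1: monitor-style 250-ms series plus duplicate-measurement correction.

Classical ultrasound fetal monitors emit one period value every 250 ms.
Because the autocorrelation window spans more than one cardiac cycle, a
single heart interval is usually reported several times (duplicates).
D1 first builds that 250-ms series (when the measurement step is 25 ms,
each slot is the median of its 10 constituent measurements) and then
converts maximal runs of equal values into the most probable number of
true cardiac events.

For a run of n slots of common value T, the candidate beat counts are
Min = (n-1)*250/T and Max = (n+1)*250/T.  When both round to the same
integer that count is the unique consistent solution; otherwise the most
probable count round(n*250/T) is used (at least one event).  Rounding is
half-up.  Runs rely on exact value equality, which holds because monitor
outputs are quantized (0.25 bpm here).
"""
from __future__ import annotations

import numpy as np

from .events import BeatEventSeries, EvenSeries

__all__ = [
    "median_fhr_250",
    "correct_duplicates",
    "extract_events_d1",
    "quantize_period",
    "monitor_series",
]

SLOT_MS = 250.0
BPM_RESOLUTION = 0.25


def quantize_period(T_ms: float) -> float:
    """Quantize a period to the monitor's 0.25 bpm rate resolution."""
    bpm = 60000.0 / T_ms
    bpm_q = np.round(bpm / BPM_RESOLUTION) * BPM_RESOLUTION
    return 60000.0 / bpm_q


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def median_fhr_250(measurements: list, quantize: bool = True) -> EvenSeries:
    """Collapse a 25-ms measurement stream into the 250-ms monitor series.

    Each slot is the median of the valid periods among its 10
    measurements, or a loss marker when more than 5 of the 10 are
    invalid.  With a 250-ms measurement step each measurement is its own
    slot.  Values are quantized to the 0.25 bpm monitor resolution so
    duplicate measurements repeat exactly.
    """
    if not measurements:
        return EvenSeries(np.empty(0))
    t = np.array([m.t for m in measurements])
    if len(t) > 1:
        step = float(np.median(np.diff(t)))
    else:
        step = SLOT_MS
    per_slot = max(1, int(round(SLOT_MS / step)))

    values = []
    for i in range(0, len(measurements) - per_slot + 1, per_slot):
        group = measurements[i : i + per_slot]
        good = [m.F for m in group if m.valid]
        n_invalid = per_slot - len(good)
        if n_invalid > per_slot // 2:
            values.append(np.nan)
            continue
        T = float(np.median(good))
        if quantize:
            T = quantize_period(T)
        values.append(T)
    t0 = measurements[0].t
    return EvenSeries(np.array(values), t0=t0, step=SLOT_MS)


def correct_duplicates(series: EvenSeries) -> BeatEventSeries:
    """Convert a 250-ms series into a time series of events.

    Loss slots break runs and leave gaps (no interpolation across loss).
    Event timestamps are laid consecutively from each run's start.
    """
    values = series.values
    events = []
    i = 0
    n_slots = len(values)
    while i < n_slots:
        if not np.isfinite(values[i]) or values[i] <= 0:
            i += 1
            continue
        T = values[i]
        j = i
        while j < n_slots and np.isfinite(values[j]) and values[j] == T:
            j += 1
        n = j - i
        mn = (n - 1) * series.step / T
        mx = (n + 1) * series.step / T
        if _round_half_up(mn) == _round_half_up(mx):
            k = _round_half_up(mn)
        else:
            k = _round_half_up(n * series.step / T)
        k = max(1, k)
        run_start = series.t0 + i * series.step
        for m in range(k):
            events.append((run_start + m * T, T, True))
        i = j
    return BeatEventSeries.from_events(_drop_overlaps(events), source="d1")


def _drop_overlaps(events: list) -> list:
    """Keep timestamps strictly increasing (runs can slightly overlap)."""
    out = []
    last_tau = -np.inf
    for tau, T, valid in events:
        if tau <= last_tau:
            continue
        out.append((tau, T, valid))
        last_tau = tau
    return out


def extract_events_d1(measurements: list) -> BeatEventSeries:
    """Full D1 chain: 250-ms median series, then duplicate correction."""
    return correct_duplicates(median_fhr_250(measurements))


def monitor_series(
    events: BeatEventSeries,
    avg_window_ms: float | None = 1500.0,
    quantize: bool = True,
) -> EvenSeries:
    """Monitor-style 250-ms rendering of an event series.

    Emulates what a classical autocorrelation monitor emits every
    250 ms, quantized to 0.25 bpm.  With ``avg_window_ms`` set, each
    tick carries the overlap-weighted mean interval over the trailing
    window (the correlation window's averaging effect) — the duplicated
    *and* smoothed representation whose beat-to-beat variability is
    systematically under-estimated.  With ``avg_window_ms=None`` the
    tick carries the interval containing it (pure sample-and-hold
    duplication, no averaging), the idealized input of the duplicate-
    correction rule.
    """
    if len(events) == 0:
        return EvenSeries(np.empty(0))
    t_last = events.tau[-1] + events.T[-1]
    if avg_window_ms is None:
        ticks = np.arange(events.tau[0], t_last + 1e-9, SLOT_MS)
        vals, covered = events.sample_at(ticks)
        values = [
            (quantize_period(v) if quantize else v) if c else np.nan
            for v, c in zip(vals, covered)
        ]
        return EvenSeries(np.array(values), t0=float(ticks[0]), step=SLOT_MS)
    ticks = np.arange(events.tau[0] + avg_window_ms, t_last + 1e-9, SLOT_MS)
    starts = events.tau
    ends = events.tau + events.T
    values = []
    for tick in ticks:
        w0 = tick - avg_window_ms
        ov = np.minimum(ends, tick) - np.maximum(starts, w0)
        ov = np.where(events.valid, np.maximum(ov, 0.0), 0.0)
        tot = ov.sum()
        if tot <= 0:
            values.append(np.nan)
            continue
        T = float(np.sum(ov * events.T) / tot)
        values.append(quantize_period(T) if quantize else T)
    return EvenSeries(np.array(values), t0=float(ticks[0]) if len(ticks) else 0.0, step=SLOT_MS)
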