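"""Method D2: segmentation of the 25-ms measurement stream into beat events.

The instantaneous period stream F_j (one value every gamma = 25 ms) is
cut into segments, one per cardiac cycle: a running median m of the
accumulated F values is kept until the elapsed segment time n*gamma
exceeds m, at which point m becomes the interval T_i and the next
segment starts.  Two refinements keep segments phase-aligned with the
actual beats:

* the analysis starts at a point P found from the envelope's RMS power
  (back up from the strongest activity in the first three seconds until
  the RMS drops below 2/3 of its maximum), so the first segment begins
  near a cycle boundary;
* the matching algorithm (MAA) checks, over the last seven intervals,
  whether the F stream fits the interval markers better when the
  markers are shifted by +/-gamma; if so, the next timestamp is nudged
  by gamma/5 = 5 ms in the improving direction.  Interval values are
  never changed by MAA, only timestamps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import BeatEventSeries
from .preprocessing import Envelope

__all__ = [
    "SegmentationState",
    "find_starting_point",
    "segment_measurements",
    "matching_correction",
    "extract_events_d2",
]

RMS_WINDOWS = (100.0, 200.0, 250.0, 500.0, 1000.0)  # [ms]


@dataclass
class SegmentationState:
    """Fixed constants of the D2 segmentation.

    gamma is the measurement repetition step; the correction quantum is
    gamma/5 (5 ms for the standard 25 ms step); MAA inspects the seven
    most recent segments.
    """

    P: float = 0.0
    gamma: float = 25.0
    maa_depth: int = 7
    epsilons: list = field(default_factory=list)  # audit: correction applied per event

    @property
    def epsilon_quantum(self) -> float:
        return self.gamma / 5.0


def find_starting_point(env: Envelope, window: float = 500.0) -> float:
    """RMS-based starting point P [ms] for segmentation.

    Sliding-window RMS (1 ms step) over the first three seconds; from
    the RMS maximum, walk backward; P is the first position where the
    RMS drops below 2/3 of that maximum.  Flat envelopes (never dropping
    below the threshold) give P = 0, as does an envelope shorter than
    three seconds.
    """
    if window not in RMS_WINDOWS:
        raise ValueError(f"window must be one of {RMS_WINDOWS}")
    n3s = int(3.0 * env.rate)
    if len(env) < n3s:
        import warnings

        warnings.warn("envelope shorter than 3 s; starting point defaults to 0", stacklevel=2)
        return 0.0
    w = int(round(window * env.rate / 1000.0))
    x = env.values[:n3s] ** 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n_pos = n3s - w + 1
    rms = np.sqrt((csum[w:] - csum[:-w]) / w)  # rms[i] = window starting at i
    peak = int(np.argmax(rms))
    threshold = (2.0 / 3.0) * rms[peak]
    below = np.nonzero(rms[: peak + 1] < threshold)[0]
    if len(below) == 0:
        return 0.0
    return env.t0 + float(below[-1]) * 1000.0 / env.rate


def segment_measurements(measurements: list, P: float = 0.0) -> BeatEventSeries:
    """Plain running-median segmentation (no matching correction).

    Analysis starts at the first measurement with t >= P.  Invalid
    measurements close the open segment as a loss gap (recorded as an
    invalid event) and segmentation restarts at the next valid value.
    """
    ms = [m for m in measurements if m.t >= P]
    if not ms:
        return BeatEventSeries.empty(source="d2")
    gamma = 25.0
    if len(ms) > 1:
        gamma = float(np.median(np.diff([m.t for m in ms])))

    events = []
    seg_vals: list = []
    seg_start: float | None = None
    gap_start: float | None = None
    for m in ms:
        if not m.valid:
            if seg_start is not None and gap_start is None:
                gap_start = seg_start
            elif gap_start is None:
                gap_start = m.t
            seg_vals = []
            seg_start = None
            continue
        if gap_start is not None:
            if m.t > gap_start:
                events.append((gap_start, m.t - gap_start, False))
            gap_start = None
        if seg_start is None:
            seg_start = m.t
        seg_vals.append(m.F)
        med = float(np.median(seg_vals))
        if len(seg_vals) * gamma > med:
            events.append((seg_start, med, True))
            seg_start = seg_start + len(seg_vals) * gamma
            seg_vals = []
    return BeatEventSeries.from_events(events, source="d2")


def _shift_score(t: np.ndarray, F: np.ndarray, bounds: np.ndarray, T_vals: np.ndarray, s: float) -> float:
    """Mean |F_j - T| over F_j inside the shifted interval markers.

    ``bounds`` are the interval boundaries (len = len(T_vals) + 1); the
    markers are shifted by ``s`` before locating each measurement.
    Returns inf when no measurement falls inside.
    """
    b = bounds + s
    mask = (t >= b[0]) & (t < b[-1])
    if not np.any(mask):
        return float("inf")
    idx = np.searchsorted(b, t[mask], side="right") - 1
    idx = np.clip(idx, 0, len(T_vals) - 1)
    return float(np.mean(np.abs(F[mask] - T_vals[idx])))


def matching_correction(
    measurements: list,
    events: BeatEventSeries,
    state: SegmentationState | None = None,
) -> BeatEventSeries:
    """Re-emit the event series with on-line matching correction (MAA).

    The first valid event of ``events`` seeds the recursion; from there
    each interval value T_i is the median of the valid F_j inside
    [tau_i, tau_i + T_{i-1}), and the next timestamp is
    tau_{i+1} = tau_i + T_{i-1} nudged by gamma/5 toward whichever
    marker shift in {-gamma, 0, +gamma} best matches the F stream over
    the last seven intervals.  Applied corrections are appended to
    ``state.epsilons`` for auditing.
    """
    if state is None:
        state = SegmentationState()
    first = next((k for k in range(len(events)) if events.valid[k]), None)
    if first is None:
        return BeatEventSeries.empty(source="d2")
    valid_ms = [m for m in measurements if m.valid]
    if not valid_ms:
        return BeatEventSeries.empty(source="d2")
    t = np.array([m.t for m in valid_ms])
    F = np.array([m.F for m in valid_ms])
    t_last = t[-1]
    gamma = state.gamma
    eps_q = state.epsilon_quantum

    out = [(float(events.tau[first]), float(events.T[first]), True)]
    state.epsilons.append(0.0)
    tau = out[0][0] + out[0][1]
    T_prev = out[0][1]
    while tau + T_prev <= t_last + gamma:
        hi = tau + T_prev
        mask = (t >= tau) & (t < hi)
        if not np.any(mask):
            # loss gap: keep walking at the previous period, flag the gap
            out.append((tau, T_prev, False))
            state.epsilons.append(0.0)
            tau = hi
            continue
        T_i = float(np.median(F[mask]))
        out.append((tau, T_i, True))

        recent = [e for e in out if e[2]][-state.maa_depth :]
        bounds = np.array([e[0] for e in recent] + [hi])
        T_vals = np.array([e[1] for e in recent])
        scores = [
            _shift_score(t, F, bounds, T_vals, s) for s in (0.0, -gamma, +gamma)
        ]
        best = int(np.argmin(scores))  # ties favour no shift
        if best == 0:
            eps = 0.0
        elif best == 1:
            eps = -eps_q  # fits better earlier: pull the next marker back
        else:
            eps = +eps_q
        state.epsilons.append(eps)
        tau = hi + eps  # next marker = end of the current window, nudged
        T_prev = T_i
    return BeatEventSeries.from_events(_monotone(out), source="d2")


def _monotone(events: list) -> list:
    out = []
    last = -np.inf
    for tau, T, valid in events:
        if tau <= last:
            continue
        out.append((tau, T, valid))
        last = tau
    return out


def extract_events_d2(
    measurements: list,
    env: Envelope | None = None,
    rms_window: float = 500.0,
    maa_enabled: bool = True,
    state: SegmentationState | None = None,
) -> BeatEventSeries:
    """Full D2 chain: starting point, segmentation, optional MAA."""
    P = find_starting_point(env, rms_window) if env is not None else 0.0
    base = segment_measurements(measurements, P)
    if not maa_enabled or len(base) == 0:
        return base
    return matching_correction(measurements, base, state)
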