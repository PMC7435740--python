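"""Artifact rejection on the beat event series.

Interferences from maternal vessels or fetal movement can shorten a
measured cardiac interval, or lengthen it when a beat is missed.  Each
interval must fall inside an asymmetric acceptance corridor around its
predecessor,

    T_{i-1} - 0.1 * Delta < T_i < T_{i-1} + 0.15 * Delta,
    Delta = T_{i-1} - 300 ms  (if T_{i-1} >= 320 ms, else 20 ms),

and must belong to a group of at least three successive corridor-
satisfying intervals.  The pass runs in both directions of the timeline
(with the asymmetric fractions mirrored on the way back) so that the
monotone slopes of accelerations and decelerations are not wrongly
discarded; only intervals rejected by *both* passes are candidates for
removal.  A final monotonicity check confirms a candidate as incorrect
when its differences to both neighbours share a sign and their product
exceeds 35 ms^2.  Validation only sets flags; values are never altered.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import BeatEventSeries

__all__ = ["ValidationParams", "corridor", "validate_bidirectional", "monotonicity_filter", "validate_events"]


@dataclass(frozen=True)
class ValidationParams:
    lower_frac: float = 0.1
    upper_frac: float = 0.15
    delta_offset: float = 300.0     # [ms]
    delta_breakpoint: float = 320.0  # [ms]
    delta_floor: float = 20.0        # [ms]
    group_min: int = 3
    mono_product_max: float = 35.0   # [ms^2]
    swap_backward: bool = True       # mirror the asymmetric fractions on the backward pass


def corridor(T_prev: float, params: ValidationParams = ValidationParams()) -> tuple:
    """Open acceptance interval (lo, hi) for the next interval."""
    if T_prev <= 0:
        raise ValueError("T_prev must be positive")
    if T_prev >= params.delta_breakpoint:
        delta = T_prev - params.delta_offset
    else:
        delta = params.delta_floor
    return (T_prev - params.lower_frac * delta, T_prev + params.upper_frac * delta)


def _directional_accept(T: np.ndarray, params: ValidationParams, lower: float, upper: float) -> np.ndarray:
    """One-direction pass: corridor satisfaction plus the group-of-three rule.

    The first interval has no predecessor and counts as corridor-
    satisfying; an interval is accepted when it sits in a run of at
    least ``group_min`` successive corridor-satisfying intervals.
    """
    n = len(T)
    ok = np.ones(n, dtype=bool)
    for i in range(1, n):
        if T[i - 1] >= params.delta_breakpoint:
            delta = T[i - 1] - params.delta_offset
        else:
            delta = params.delta_floor
        lo = T[i - 1] - lower * delta
        hi = T[i - 1] + upper * delta
        ok[i] = lo < T[i] < hi
    accept = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        if j - i >= params.group_min:
            accept[i:j] = True
        i = j
    return accept


def validate_bidirectional(events: BeatEventSeries, params: ValidationParams = ValidationParams()) -> np.ndarray:
    """Accept flags from the two-directional corridor validation.

    Only intervals rejected in both directions are flagged unacceptable.
    Invalid (loss) events are ignored: they are already rejected, and
    the corridor chains restart after each gap.
    """
    n = len(events)
    accept = np.array(events.valid, dtype=bool)
    idx = np.nonzero(events.valid)[0]
    if len(idx) < params.group_min:
        import warnings

        warnings.warn("fewer events than the minimum group size; validation indeterminate", stacklevel=2)
        return accept
    # split the valid events into chains not interrupted by loss gaps
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    chains = np.split(idx, breaks + 1)
    for chain in chains:
        T = events.T[chain]
        fwd = _directional_accept(T, params, params.lower_frac, params.upper_frac)
        if params.swap_backward:
            bwd = _directional_accept(T[::-1], params, params.upper_frac, params.lower_frac)[::-1]
        else:
            bwd = _directional_accept(T[::-1], params, params.lower_frac, params.upper_frac)[::-1]
        accept[chain] = fwd | bwd
    return accept


def monotonicity_filter(
    events: BeatEventSeries,
    candidates: np.ndarray,
    params: ValidationParams = ValidationParams(),
) -> np.ndarray:
    """Final verification of corridor-rejected intervals.

    A candidate is confirmed incorrect only when its differences to both
    neighbouring intervals have the same sign and their product exceeds
    ``mono_product_max``; otherwise it is rescued.  Returns the final
    accept flags.
    """
    T = events.T
    n = len(T)
    accept = ~np.asarray(candidates, dtype=bool)
    for i in range(n):
        if accept[i]:
            continue
        if i == 0 or i == n - 1 or not (events.valid[i - 1] and events.valid[i + 1]):
            accept[i] = True  # no two valid neighbours: cannot confirm
            continue
        d_prev = T[i] - T[i - 1]
        d_next = T[i] - T[i + 1]
        confirmed = (np.sign(d_prev) == np.sign(d_next)) and (d_prev * d_next > params.mono_product_max)
        accept[i] = not confirmed
    accept &= events.valid
    return accept


def validate_events(events: BeatEventSeries, params: ValidationParams = ValidationParams()) -> BeatEventSeries:
    """Full validation chain; returns the series with updated valid flags."""
    if len(events) == 0:
        return events
    accept = validate_bidirectional(events, params)
    candidates = events.valid & ~accept
    final = monotonicity_filter(events, candidates, params)
    return BeatEventSeries(events.tau, events.T, final & events.valid, source=events.source)
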