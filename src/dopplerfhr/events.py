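"""Shared event-series containers.

The whole package revolves around two representations of a fetal heart
rate signal:

* an evenly spaced monitor-style series (one period value every 250 ms,
  possibly with loss markers), and
* a *time series of events*: one measurement per cardiac cycle, each
  event carrying its onset timestamp tau [ms] and interval T [ms] — the
  same form a beat detector on a direct fetal ECG would produce.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BeatEventSeries", "EvenSeries"]


@dataclass
class BeatEventSeries:
    """Ordered cardiac events: onset times tau [ms] and intervals T [ms].

    ``valid`` marks events that carry a real interval measurement; an
    invalid event is a loss gap whose T spans the gap duration.  ``source``
    tags the producer (``reference``, ``d1``, ``d2`` or ``monitor``).
    """

    tau: np.ndarray
    T: np.ndarray
    valid: np.ndarray
    source: str = "reference"

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.tau) == len(self.T) == len(self.valid)):
            raise ValueError("tau, T and valid must have equal length")
        if len(self.tau) > 1 and np.any(np.diff(self.tau) <= 0):
            bad = np.nonzero(np.diff(self.tau) <= 0)[0]
            raise ValueError(f"tau must be strictly increasing; offending rows: {bad.tolist()}")
        if np.any(self.T[self.valid] <= 0):
            raise ValueError("valid events must have T > 0")

    def __len__(self) -> int:
        return len(self.tau)

    @classmethod
    def empty(cls, source: str = "reference") -> "BeatEventSeries":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=bool), source=source)

    @classmethod
    def from_events(cls, events, source: str = "reference") -> "BeatEventSeries":
        """Build from an iterable of (tau, T, valid) triples."""
        events = list(events)
        if not events:
            return cls.empty(source)
        tau, T, valid = zip(*events)
        return cls(np.array(tau, float), np.array(T, float), np.array(valid, bool), source=source)

    def sample_at(self, t: np.ndarray, offset: float = 0.0):
        """Interval value covering each query time.

        ``offset`` is this series' time offset relative to the query
        timeline (query time ``t`` maps to series time ``t + offset``).
        Returns ``(values, covered)`` where ``covered`` is False wherever
        no valid event contains the mapped time.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float)) + offset
        values = np.full(t.shape, np.nan)
        covered = np.zeros(t.shape, dtype=bool)
        if len(self.tau) == 0:
            return values, covered
        idx = np.searchsorted(self.tau, t, side="right") - 1
        ok = idx >= 0
        idx_c = np.clip(idx, 0, len(self.tau) - 1)
        inside = ok & (t < self.tau[idx_c] + self.T[idx_c]) & self.valid[idx_c]
        values[inside] = self.T[idx_c[inside]]
        covered[:] = inside
        return values, covered

    @property
    def span_ms(self) -> float:
        if len(self.tau) == 0:
            return 0.0
        return float(self.tau[-1] + self.T[-1] - self.tau[0])


@dataclass
class EvenSeries:
    """Monitor-style evenly spaced period series (one slot per ``step`` ms).

    ``values`` holds the period [ms] per slot; NaN is the loss marker.
    """

    values: np.ndarray
    t0: float = 0.0
    step: float = 250.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(len(self.values))

    def is_loss(self) -> np.ndarray:
        return ~np.isfinite(self.values)
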