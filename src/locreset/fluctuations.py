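"""Detection of localization fluctuations ("resets") in N/C time series.

A fluctuation is a continuously increasing or decreasing stretch of the N/C
trace whose net amplitude is at least 0.12 (N/C units).  Continuity is
broken wherever the signal fails to change by at least 0.005 over a sliding
3-frame window (the stagnation rule).  Events are maximal: within each
monotone stretch, runs extend until a stagnant window or a direction change
breaks them.  Detection is invariant to adding a constant to the trace and
equivariant under sign flip (increase and decrease swap).

Comparisons against the two printed thresholds use a 1e-12 absolute guard
so that traces constructed exactly at a boundary are classified by the
intended real-arithmetic rule rather than by the rounding direction of
binary floating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FluctuationEvent", "CohortStats", "detect", "cohort_stats",
           "events_to_dataframe"]

_EPS = 1e-12


@dataclass(frozen=True)
class FluctuationEvent:
    """One detected monotone excursion of the N/C trace."""

    track_id: int
    start: int
    end: int
    direction: str  # "increase" | "decrease"
    amplitude: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event must span more than one frame")
        if self.amplitude < 0:
            raise ValueError("amplitude is an absolute net change")


@dataclass
class CohortStats:
    """Cohort summary: fraction fluctuating, per-cell frequency, amplitudes."""

    fraction: float
    frequencies: pd.Series  # events per unit time, indexed by track id
    amplitudes: np.ndarray
    n_tracks: int
    n_events: int


def _monotone_stretches(x: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal stretches (start, end, sign) of non-strict monotone movement.

    Zero steps continue the current direction; a stretch ends where the
    step sign strictly reverses.  Stretches shorter than one step or with
    no strict movement are dropped.
    """
    n = len(x)
    if n < 2:
        return []
    d = np.sign(np.diff(x))
    out = []
    start, cur = 0, 0
    for i, s in enumerate(d):
        if cur == 0:
            cur = int(s)
            continue
        if s != 0 and s != cur:
            out.append((start, i, cur))
            start, cur = i, int(s)
    if cur != 0:
        out.append((start, n - 1, cur))
    return out


def _split_at_stagnation(x: np.ndarray, s: int, e: int, delta: float,
                         window: int) -> list[tuple[int, int]]:
    """Maximal subintervals of [s, e] free of stagnant sliding windows.

    A window starting at k (spanning ``window`` frames) is stagnant when
    |x[k+w-1] - x[k]| < delta.  A subinterval [a, b] is valid iff it contains
    no stagnant window entirely, i.e. no stagnant k with a <= k <= b-w+1.
    """
    w = window
    bad = [k for k in range(s, e - w + 2)
           if abs(x[k + w - 1] - x[k]) < delta - _EPS]
    bounds = [s] + [k + w - 2 for k in bad] + [e]
    starts = [s] + [k + 1 for k in bad]
    out = []
    for a, b in zip(starts, bounds[1:]):
        if b > a:
            out.append((a, b))
    return out


def detect(trace: np.ndarray, track_id: int = 0, amp_min: float = 0.12,
           stagnation_delta: float = 0.005,
           stagnation_window: int = 3) -> list[FluctuationEvent]:
    """Scan one N/C trace for localization fluctuations.

    Missing frames (NaN) split the trace into independently scanned
    segments.  Within each segment, maximal monotone runs are broken at
    stagnant windows; surviving runs with net amplitude >= ``amp_min`` are
    emitted with their direction.
    """
    x = np.asarray(trace, dtype=float)
    events: list[FluctuationEvent] = []
    isok = np.isfinite(x)
    seg_starts = np.flatnonzero(isok & ~np.r_[False, isok[:-1]])
    seg_ends = np.flatnonzero(isok & ~np.r_[isok[1:], False])
    for s0, e0 in zip(seg_starts, seg_ends):
        if e0 - s0 + 1 < stagnation_window:
            continue
        seg = x[s0:e0 + 1]
        for a, b, sign in _monotone_stretches(seg):
            for ra, rb in _split_at_stagnation(seg, a, b, stagnation_delta,
                                               stagnation_window):
                amp = abs(seg[rb] - seg[ra])
                if amp >= amp_min - _EPS:
                    events.append(FluctuationEvent(
                        track_id=track_id, start=int(s0 + ra), end=int(s0 + rb),
                        direction="increase" if sign > 0 else "decrease",
                        amplitude=float(amp)))
    return events


def cohort_stats(events: list[FluctuationEvent], track_ids: list[int],
                 observation_span: float) -> CohortStats:
    """Fraction of cells with >= 1 event and per-cell event frequency.

    ``observation_span`` is the observed duration per track in the caller's
    time unit; frequencies are events per that unit.
    """
    if len(track_ids) == 0:
        raise ValueError("cohort has no tracks")
    if observation_span <= 0:
        raise ValueError("observation span must be positive")
    ids = set(track_ids)
    for ev in events:
        if ev.track_id not in ids:
            raise ValueError(f"event references unknown track {ev.track_id}")
    counts = pd.Series(0, index=sorted(ids), dtype=int)
    for ev in events:
        counts[ev.track_id] += 1
    fraction = float((counts > 0).sum() / len(counts))
    return CohortStats(
        fraction=fraction,
        frequencies=counts / observation_span,
        amplitudes=np.array([ev.amplitude for ev in events]),
        n_tracks=len(counts),
        n_events=len(events),
    )


def events_to_dataframe(events: list[FluctuationEvent]) -> pd.DataFrame:
    cols = ["track_id", "start_frame", "end_frame", "direction", "amplitude"]
    rows = [{"track_id": e.track_id, "start_frame": e.start, "end_frame": e.end,
             "direction": e.direction, "amplitude": e.amplitude} for e in events]
    return pd.DataFrame(rows, columns=cols)
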