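"""Warning-light protocol: preictal-change detections and persistent warnings.

A *preictal change* is signaled when five consecutive 1-min windows on the
15-s grid are classified 'preictal' — i.e. two minutes of signal
continuously classified preictal; while the run persists, a detection is
emitted at every further grid step.  Each detection raises (or extends) a
warning that stays active until ``persistence_tau`` minutes after the most
recent detection; overlapping active periods merge into a single counted
warning.  A warning whose active period runs into a recording interruption
longer than three minutes is discarded, and both the warning span and the
gap span are excluded from the assessed test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import INVALID, PREICTAL
from .exceptions import ParameterError

__all__ = ["WarningTimeline", "detect_preictal_changes", "build_warning_timeline"]

#: interruptions longer than this (seconds) invalidate a warning
MAX_ASSESSABLE_GAP_S = 180.0


@dataclass
class WarningTimeline:
    """Detections, merged active-warning intervals, and assessed time."""

    detections: np.ndarray  # detection times, s
    warnings: list[tuple[float, float]]  # counted [start, end) intervals
    persistence_tau: float  # minutes
    discarded_warnings: list[tuple[float, float]] = field(default_factory=list)
    total_test_time: float = 0.0  # assessed seconds (span minus discarded time)
    span: tuple[float, float] = (0.0, 0.0)

    @property
    def total_warning_time(self) -> float:
        return sum(b - a for a, b in self.warnings)

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)

    def detections_in(self, interval: tuple[float, float]) -> np.ndarray:
        a, b = interval
        return self.detections[(self.detections >= a - 1e-9) & (self.detections < b)]


def detect_preictal_changes(
    window_labels: np.ndarray,
    window_starts: np.ndarray,
    k: int = 5,
    window_length: float = 60.0,
) -> np.ndarray:
    """Detection times from the window-label stream on the 15-s grid.

    A detection is emitted at the end time of every window that closes a run
    of at least ``k`` consecutive 'preictal' windows (so a sustained run
    keeps detecting at each grid step).  Invalid windows break runs.
    """
    labels = np.asarray(window_labels)
    starts = np.asarray(window_starts, float)
    if labels.shape != starts.shape:
        raise ParameterError("labels and window starts must align")
    run = 0
    times = []
    for lab, t in zip(labels, starts):
        run = run + 1 if lab == PREICTAL else 0
        if lab == INVALID:
            run = 0
        if run >= k:
            times.append(t + window_length)
    return np.asarray(times, float)


def _merge_active_periods(
    detections: np.ndarray, tau_s: float, span: tuple[float, float]
) -> list[tuple[float, float, list[float]]]:
    """Merged [start, end) active periods, each with its member detections."""
    periods: list[tuple[float, float, list[float]]] = []
    for t in np.sort(detections):
        end = min(t + tau_s, span[1])
        if periods and t <= periods[-1][1]:
            a, b, ds = periods.pop()
            ds.append(t)
            periods.append((a, max(b, end), ds))
        else:
            periods.append((t, end, [t]))
    return periods


def build_warning_timeline(
    detections: np.ndarray,
    persistence_tau: float,
    gaps: list[tuple[float, float]],
    span: tuple[float, float],
    max_gap: float = MAX_ASSESSABLE_GAP_S,
) -> WarningTimeline:
    """Turn detections into merged, persistence-tau warnings over ``span``.

    ``persistence_tau`` is in minutes.  Each detection extends the active
    period to ``detection + tau``; overlapping periods merge and count as
    one warning.  A period that intersects a gap longer than ``max_gap``
    seconds beginning before the period ends is discarded.  Assessed time is
    the span minus discarded warning spans and minus all gaps longer than
    ``max_gap``.
    """
    if persistence_tau < 0:
        raise ParameterError("persistence_tau must be nonnegative")
    tau_s = persistence_tau * 60.0
    detections = np.asarray(detections, float)
    long_gaps = [(a, b) for a, b in gaps if (b - a) > max_gap]
    periods = _merge_active_periods(detections, tau_s, span)
    kept: list[tuple[float, float]] = []
    discarded: list[tuple[float, float]] = []
    for a, b, _ in periods:
        if any(ga < b and a < gb for ga, gb in long_gaps):
            discarded.append((a, b))
        else:
            kept.append((a, b))
    excluded = _interval_union_length(discarded + long_gaps)
    return WarningTimeline(
        detections=detections,
        warnings=kept,
        persistence_tau=persistence_tau,
        discarded_warnings=discarded,
        total_test_time=(span[1] - span[0]) - excluded,
        span=span,
    )


def _interval_union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    total = 0.0
    cur_a, cur_b = None, None
    for a, b in sorted(intervals):
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return total
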