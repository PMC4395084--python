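"""Prediction performance statistics and statistical validation.

Metrics per persistence-tau: sensitivity (fraction of test seizures whose
onset falls inside an active warning), proportion of assessed time under
warning (rho), warning rate and Mormann-convention false-prediction rate
(false warnings per hour after excluding the assumed preictal time, N tau).
Statistical validation compares the achieved sensitivity with that of a
chance predictor, whose sensitivity equals rho: the one-sided binomial
p-value

    p = P( Binomial(N, rho) >= n ),   valid for n/N >= rho,

with Benjamini-Hochberg q-values across a comparison grid, plus linear
interpolation of all metrics at the clinically critical false-prediction
rate (3.6 seizures/day = 0.15/h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .exceptions import ParameterError
from .warning_protocol import WarningTimeline

__all__ = [
    "PerformanceReport",
    "sensitivity",
    "time_metrics",
    "false_prediction_rate",
    "chance_p_value",
    "bh_qvalues",
    "prediction_time",
    "performance_at_critical_fpr",
    "chance_predictor_simulate",
    "critical_rate_per_hour",
    "evaluate_timeline",
]

#: clinically critical false-prediction rate, warnings per hour
CRITICAL_FPR_PER_H = 0.15


def critical_rate_per_hour(seizures_per_day: float = 3.6) -> float:
    """Convert a daily seizure frequency to the hourly critical rate (3.6/day -> 0.15/h)."""
    return seizures_per_day / 24.0


@dataclass
class PerformanceReport:
    """Per-persistence-tau performance summary."""

    persistence_tau: float  # minutes
    n_predicted: int
    n_seizures: int
    sensitivity: float
    rho: float  # proportion of assessed time under warning
    warning_rate: float  # warnings per assessed hour
    fpr: float  # false warnings per hour, Mormann convention
    p_chance: float
    q_value: float | None = None
    mean_prediction_time_min: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _assessed_hours(timeline: WarningTimeline) -> float:
    return timeline.total_test_time / 3600.0


def _onset_predicted(timeline: WarningTimeline, onset: float) -> bool:
    return any(a <= onset < b for a, b in timeline.warnings)


def sensitivity(timeline: WarningTimeline, onsets) -> tuple[int, int, float]:
    """(n predicted, N total, fraction): onset inside an active warning counts."""
    onsets = list(onsets)
    N = len(onsets)
    if N == 0:
        raise ParameterError("no test seizures: sensitivity undefined")
    n = sum(_onset_predicted(timeline, t) for t in onsets)
    return n, N, n / N


def time_metrics(timeline: WarningTimeline) -> tuple[float, float]:
    """(rho, warning rate per hour) over the assessed test time."""
    hours = _assessed_hours(timeline)
    if hours <= 0:
        raise ParameterError("assessed test time is zero")
    rho = timeline.total_warning_time / timeline.total_test_time
    return rho, timeline.n_warnings / hours


def false_prediction_rate(timeline: WarningTimeline, onsets, persistence_tau: float) -> float:
    """False warnings per hour, excluding assumed preictal time N*tau (Mormann)."""
    onsets = list(onsets)
    false_warnings = sum(
        not any(a <= t < b for t in onsets) for a, b in timeline.warnings
    )
    denom_h = _assessed_hours(timeline) - len(onsets) * persistence_tau / 60.0
    if denom_h <= 0:
        raise ParameterError(
            "assessed time does not exceed the assumed preictal time N*tau"
        )
    return false_warnings / denom_h


def chance_p_value(n: int, N: int, rho: float) -> float:
    """One-sided p-value of beating a chance predictor of sensitivity rho.

    ``p = 1 - sum_{k<n} C(N,k) rho^k (1-rho)^(N-k) = P(Binomial(N, rho) >= n)``,
    evaluated through the numerically stable binomial survival function.
    Stated for ``n/N >= rho``; a violated precondition raises.
    """
    if not 0 <= n <= N:
        raise ParameterError("need 0 <= n <= N")
    if not 0.0 <= rho <= 1.0:
        raise ParameterError("rho must be in [0, 1]")
    if N > 0 and n / N < rho:
        raise ParameterError("one-sided test requires n/N >= rho")
    if n == 0:
        return 1.0
    return float(spstats.binom.sf(n - 1, N, rho))


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} m p_(j) / j``, capped at 1.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def prediction_time(timeline: WarningTimeline, onsets) -> float:
    """Mean minutes from the first detection of each predicting warning to onset."""
    leads = []
    for t in onsets:
        for a, b in timeline.warnings:
            if a <= t < b:
                ds = timeline.detections_in((a, b))
                ds = ds[ds <= t]
                if ds.size:
                    leads.append((t - ds.min()) / 60.0)
                break
    if not leads:
        raise ParameterError("no predicted seizures: prediction time undefined")
    return float(np.mean(leads))


def performance_at_critical_fpr(
    reports: list[PerformanceReport], critical: float = CRITICAL_FPR_PER_H
) -> dict:
    """Linear interpolation of all metrics at the critical false-prediction rate.

    Reports are taken in increasing persistence-tau order; the first pair of
    consecutive tau values whose fpr brackets ``critical`` is interpolated.
    An exact hit returns that report's row unmodified.  If the fpr curve
    never reaches the critical value, the closest endpoint is returned with
    ``extrapolated=True``.
    """
    reps = sorted(reports, key=lambda r: r.persistence_tau)
    if not reps:
        raise ParameterError("no reports to interpolate")
    fields = [
        "persistence_tau", "sensitivity", "rho", "warning_rate", "fpr",
        "mean_prediction_time_min",
    ]
    for r in reps:
        if r.fpr == critical:
            return {f: getattr(r, f) for f in fields} | {"extrapolated": False}
    for lo, hi in zip(reps, reps[1:]):
        f0, f1 = lo.fpr, hi.fpr
        if min(f0, f1) < critical < max(f0, f1):
            w = (critical - f0) / (f1 - f0)
            out = {}
            for f in fields:
                a, b = getattr(lo, f), getattr(hi, f)
                out[f] = None if a is None or b is None else a + w * (b - a)
            out["fpr"] = critical
            out["extrapolated"] = False
            return out
    nearest = min(reps, key=lambda r: abs(r.fpr - critical))
    return {f: getattr(nearest, f) for f in fields} | {"extrapolated": True}


def chance_predictor_simulate(
    rho: float, onsets, span: tuple[float, float], n_sims: int = 10000, seed=None
) -> np.ndarray:
    """Empirical sensitivity of random warnings occupying a fraction rho of the span.

    Each simulation places a warning set of total length ``rho * span`` at a
    uniformly random circular offset, so each onset is covered with
    probability exactly rho — the identity underpinning the chance-predictor
    test.  Returns one sensitivity per simulation.
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError("rho must be in [0, 1]")
    onsets = np.asarray(list(onsets), float)
    if onsets.size == 0:
        raise ParameterError("need at least one onset")
    a, b = span
    length = b - a
    rng = np.random.default_rng(seed)
    starts = rng.random(n_sims) * length
    pos = (onsets[None, :] - a - starts[:, None]) % length
    covered = pos < rho * length
    return covered.mean(axis=1)


def evaluate_timeline(
    timeline: WarningTimeline, onsets, q_value: float | None = None
) -> PerformanceReport:
    """Assemble the full performance report for one timeline."""
    n, N, sens = sensitivity(timeline, onsets)
    rho, rate = time_metrics(timeline)
    try:
        fpr = false_prediction_rate(timeline, onsets, timeline.persistence_tau)
    except ParameterError:
        fpr = float("nan")  # assumed preictal time N*tau exhausts the assessed span
    p = chance_p_value(n, N, rho) if (N > 0 and n / N >= rho) else 1.0
    try:
        lead = prediction_time(timeline, onsets)
    except ParameterError:
        lead = None
    return PerformanceReport(
        persistence_tau=timeline.persistence_tau,
        n_predicted=n,
        n_seizures=N,
        sensitivity=sens,
        rho=rho,
        warning_rate=rate,
        fpr=fpr,
        p_chance=p,
        q_value=q_value,
        mean_prediction_time_min=lead,
    )
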