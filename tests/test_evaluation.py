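"""Performance metrics, chance-predictor validation, BH correction."""

import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from mfwarn.evaluation import (
    PerformanceReport,
    bh_qvalues,
    chance_p_value,
    chance_predictor_simulate,
    critical_rate_per_hour,
    evaluate_timeline,
    false_prediction_rate,
    performance_at_critical_fpr,
    prediction_time,
    sensitivity,
    time_metrics,
)
from mfwarn.exceptions import ParameterError
from mfwarn.warning_protocol import WarningTimeline


def timeline(warnings, span=(0.0, 36000.0), detections=None, tau=30.0):
    det = np.asarray(
        detections if detections is not None else [a for a, _ in warnings], float
    )
    return WarningTimeline(
        detections=det,
        warnings=list(warnings),
        persistence_tau=tau,
        total_test_time=span[1] - span[0],
        span=span,
    )


def brute_force_chance_p(n, N, rho):
    return 1.0 - sum(
        math.comb(N, k) * rho**k * (1 - rho) ** (N - k) for k in range(n)
    )


class TestSensitivity:
    def test_toy_timeline(self):
        n, N, frac = sensitivity(timeline([(90.0, 200.0)]), [100.0, 500.0])
        assert (n, N, frac) == (1, 2, 0.5)

    def test_no_warnings(self):
        assert sensitivity(timeline([]), [100.0])[2] == 0.0

    def test_full_cover(self):
        assert sensitivity(timeline([(0.0, 36000.0)]), [5.0, 600.0])[2] == 1.0

    def test_onset_at_warning_end_unpredicted(self):
        assert sensitivity(timeline([(0.0, 100.0)]), [100.0])[0] == 0

    def test_no_seizures_flagged(self):
        with pytest.raises(ParameterError):
            sensitivity(timeline([]), [])


class TestTimeMetrics:
    def test_direct_arithmetic(self):
        rho, rate = time_metrics(timeline([(0.0, 1800.0)]))
        assert rho == pytest.approx(0.05)
        assert rate == pytest.approx(0.1)

    def test_no_warnings(self):
        assert time_metrics(timeline([])) == (0.0, 0.0)

    def test_merged_period_counts_once(self):
        rho, rate = time_metrics(timeline([(0.0, 2400.0)], detections=[0.0, 600.0]))
        assert rate == pytest.approx(0.1)


class TestFalsePredictionRate:
    def test_hand_arithmetic(self):
        tl = timeline(
            [(100.0, 1900.0), (5000.0, 6800.0), (20000.0, 21800.0)],
            span=(0.0, 12 * 3600.0),
        )
        tl.total_test_time = 12 * 3600.0
        fpr = false_prediction_rate(tl, [150.0, 40000.0], 30.0)
        assert fpr == pytest.approx(2.0 / 11.0)

    def test_all_warnings_hit(self):
        tl = timeline([(100.0, 1900.0)], span=(0.0, 36000.0))
        assert false_prediction_rate(tl, [150.0], 30.0) == 0.0

    def test_zero_tau_uses_full_assessed_time(self):
        tl = timeline([(100.0, 1900.0)], span=(0.0, 36000.0))
        assert false_prediction_rate(tl, [], 0.0) == pytest.approx(0.1)

    def test_exhausted_denominator_rejected(self):
        tl = timeline([], span=(0.0, 3600.0))
        with pytest.raises(ParameterError):
            false_prediction_rate(tl, [600.0, 1200.0], 30.0)


class TestChancePValue:
    def test_zero_predicted_gives_one(self):
        assert chance_p_value(0, 5, 0.0) == 1.0

    def test_all_predicted_closed_form(self):
        assert chance_p_value(3, 3, 0.5) == pytest.approx(0.125, abs=1e-15)

    @pytest.mark.parametrize(
        "n,N,rho",
        [(2, 5, 0.1), (8, 10, 0.3), (15, 20, 0.5), (4, 4, 0.25), (1, 3, 0.05)],
    )
    def test_matches_brute_force_summation(self, n, N, rho):
        assert chance_p_value(n, N, rho) == pytest.approx(
            brute_force_chance_p(n, N, rho), abs=1e-12
        )

    def test_printed_example_value(self):
        assert chance_p_value(8, 10, 0.3) == pytest.approx(1.59e-3, rel=0.01)

    def test_precondition_enforced(self):
        with pytest.raises(ParameterError):
            chance_p_value(1, 10, 0.5)  # n/N < rho
        with pytest.raises(ParameterError):
            chance_p_value(5, 4, 0.1)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.037])[0] == pytest.approx(0.037)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_sorted_input_gives_nondecreasing_q(self, rng):
        p = np.sort(rng.random(50))
        q = bh_qvalues(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_matches_statsmodels_reference(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_qvalues(p), q_ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_qvalues([0.5, 1.5])


class TestPredictionTime:
    def test_single_detection_thirty_minutes_ahead(self):
        tl = timeline([(0.0, 2400.0)], detections=[0.0])
        assert prediction_time(tl, [1800.0]) == pytest.approx(30.0)

    def test_mean_over_predicted_seizures(self):
        tl = timeline(
            [(0.0, 3000.0), (9000.0, 12600.0)], detections=[0.0, 9000.0]
        )
        # leads: 20 min and 40 min
        assert prediction_time(tl, [1200.0, 11400.0]) == pytest.approx(30.0)

    def test_unpredicted_seizure_ignored(self):
        tl = timeline([(0.0, 2400.0)], detections=[0.0])
        assert prediction_time(tl, [1800.0, 30000.0]) == pytest.approx(30.0)

    def test_none_predicted_flagged(self):
        with pytest.raises(ParameterError):
            prediction_time(timeline([]), [100.0])


def report(tau, fpr, sens, rho=0.2):
    return PerformanceReport(
        persistence_tau=tau, n_predicted=3, n_seizures=4, sensitivity=sens,
        rho=rho, warning_rate=0.3, fpr=fpr, p_chance=0.01,
        mean_prediction_time_min=tau,
    )


class TestCriticalRate:
    def test_conversion_from_daily_frequency(self):
        assert critical_rate_per_hour(3.6) == 0.15

    def test_linear_bracket_midpoint(self):
        out = performance_at_critical_fpr([report(20, 0.2, 0.7), report(40, 0.1, 0.9)])
        assert out["persistence_tau"] == pytest.approx(30.0)
        assert out["sensitivity"] == pytest.approx(0.8)
        assert out["fpr"] == 0.15
        assert not out["extrapolated"]

    def test_exact_hit_returned_unmodified(self):
        out = performance_at_critical_fpr([report(20, 0.15, 0.7), report(40, 0.05, 0.9)])
        assert out["sensitivity"] == 0.7
        assert out["persistence_tau"] == 20

    def test_non_monotone_uses_first_bracket(self):
        reps = [report(10, 0.3, 0.5), report(20, 0.1, 0.7),
                report(30, 0.2, 0.8), report(40, 0.1, 0.9)]
        out = performance_at_critical_fpr(reps)
        assert 10 < out["persistence_tau"] < 20

    def test_out_of_range_reports_endpoint_with_flag(self):
        out = performance_at_critical_fpr([report(20, 0.5, 0.7), report(40, 0.3, 0.9)])
        assert out["extrapolated"]
        assert out["persistence_tau"] == 40


class TestChanceSimulation:
    def test_rho_zero_never_covers(self):
        s = chance_predictor_simulate(0.0, [100.0, 900.0], (0.0, 3600.0), 200, seed=0)
        assert np.all(s == 0.0)

    def test_rho_one_always_covers(self):
        s = chance_predictor_simulate(1.0, [100.0, 900.0], (0.0, 3600.0), 200, seed=0)
        assert np.all(s == 1.0)

    def test_mean_sensitivity_equals_rho(self):
        s = chance_predictor_simulate(
            0.25, np.linspace(100, 3500, 10), (0.0, 3600.0), 4000, seed=1
        )
        assert s.mean() == pytest.approx(0.25, abs=0.02)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ParameterError):
            chance_predictor_simulate(1.2, [1.0], (0.0, 10.0), 10, seed=0)


class TestEvaluateTimeline:
    def test_assembles_consistent_report(self):
        tl = timeline([(90.0, 1890.0)], span=(0.0, 36000.0), detections=[90.0], tau=30.0)
        rep = evaluate_timeline(tl, [1000.0])
        assert rep.n_predicted == 1 and rep.n_seizures == 1
        assert rep.sensitivity == 1.0
        assert rep.rho == pytest.approx(1800.0 / 36000.0)
        assert rep.fpr == 0.0
        assert rep.p_chance == pytest.approx(rep.rho)  # P(Bin(1, rho) >= 1)
        assert rep.mean_prediction_time_min == pytest.approx((1000.0 - 90.0) / 60.0)
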