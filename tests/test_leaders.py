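"""Core numerics: pyramid, wavelet leaders, structure functions, cumulants."""

import numpy as np
import pytest

from mfwarn.exceptions import ParameterError, ScaleFeasibilityError, StructuralError
from mfwarn.leaders import (
    LeaderPyramid,
    StructureFunctions,
    bootstrap_cumulants,
    compute_leaders,
    dwt_pyramid,
    log_cumulants,
    structure_functions,
    zeta_estimates,
)
from mfwarn.synthetic import simulate_fbm, simulate_mrw


def brute_force_leaders(pyramid: LeaderPyramid, j: int, k: int) -> float:
    """Leader by exhaustive enumeration of dyadic intervals in the 3-neighborhood.

    lambda_{j',k'} = [k' 2^j', (k'+1) 2^j') is included iff it lies inside
    [(k-1) 2^j, (k+2) 2^j) and j' <= j.
    """
    lo, hi = (k - 1) * 2**j, (k + 2) * 2**j
    vals = []
    for jp in range(1, j + 1):
        d = pyramid.coefficients[jp - 1]
        for kp in range(d.shape[-1]):
            if kp * 2**jp >= lo and (kp + 1) * 2**jp <= hi:
                vals.append(abs(d[kp]))
    return max(vals)


def constant_leader_pyramid(values_per_scale, n_per_scale):
    """A pyramid with fabricated leaders (coefficients unused)."""
    leaders = [np.full(n, v, float) for v, n in zip(values_per_scale, n_per_scale)]
    valid = [np.ones(n, bool) for n in n_per_scale]
    return LeaderPyramid(
        coefficients=[ld.copy() for ld in leaders],
        coefficient_valid=[v.copy() for v in valid],
        leaders=leaders,
        leader_valid=valid,
    )


class TestPyramid:
    def test_zero_signal_all_zero_coefficients(self):
        pyr = dwt_pyramid(np.zeros(1024), 4)
        for d in pyr.coefficients:
            assert np.all(d == 0.0)

    def test_three_vanishing_moments_annihilate_quadratics(self):
        t = np.linspace(0, 1, 4096)
        sig = 3.0 + 2.0 * t - 5.0 * t**2
        pyr = dwt_pyramid(sig, 5)
        norm = np.linalg.norm(sig)
        for d, v in zip(pyr.coefficients, pyr.coefficient_valid):
            assert np.all(np.abs(d[v]) < 1e-8 * norm)

    def test_coefficient_counts_follow_dyadic_decimation(self, rng):
        sig = rng.standard_normal(4096)
        pyr = dwt_pyramid(sig, 6)
        for j, d in enumerate(pyr.coefficients, start=1):
            assert d.shape[-1] == 4096 // 2**j

    def test_scale_feasibility_error_names_max_octave(self):
        with pytest.raises(ScaleFeasibilityError) as err:
            dwt_pyramid(np.zeros(256), 8)
        assert err.value.max_feasible == 5  # floor(log2(256/6))

    def test_batch_axis_matches_loop(self, rng):
        batch = rng.standard_normal((7, 512))
        pyr = dwt_pyramid(batch, 4)
        for row in range(7):
            single = dwt_pyramid(batch[row], 4)
            for d2, d1 in zip(pyr.coefficients, single.coefficients):
                np.testing.assert_allclose(d2[row], d1, atol=1e-12)

    def test_l1_normalization_scales_as_2_jh(self, rng):
        # for fBm, median |d(j,.)| grows as 2^{jH} under L1 normalization
        sig = simulate_fbm(0.8, 2**15, seed=0)
        pyr = dwt_pyramid(sig, 7)
        med = [np.median(np.abs(d[v])) for d, v in
               zip(pyr.coefficients, pyr.coefficient_valid)]
        slope = np.polyfit(np.arange(1, 8), np.log2(med), 1)[0]
        assert slope == pytest.approx(0.8, abs=0.12)


class TestLeaders:
    def test_zero_coefficients_zero_leaders(self):
        pyr = compute_leaders(dwt_pyramid(np.zeros(512), 4))
        for lead, v in zip(pyr.leaders, pyr.leader_valid):
            assert np.all(lead[v] == 0.0)

    def test_missing_coefficients_raise(self):
        with pytest.raises(StructuralError):
            compute_leaders(LeaderPyramid(coefficients=[], coefficient_valid=[]))

    def test_leader_dominates_own_coefficient(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(1024), 5))
        for d, lead, v in zip(pyr.coefficients, pyr.leaders, pyr.leader_valid):
            assert np.all(lead[v] >= np.abs(d[v]) - 1e-15)

    def test_matches_brute_force_enumeration(self, rng):
        sig = rng.standard_normal(256)
        pyr = compute_leaders(dwt_pyramid(sig, 4))
        for j in range(1, 5):
            lead, v = pyr.leaders[j - 1], pyr.leader_valid[j - 1]
            for k in np.flatnonzero(v):
                assert lead[k] == pytest.approx(
                    brute_force_leaders(pyr, j, int(k)), rel=1e-12
                )

    def test_n_per_scale_non_increasing(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(2048), 6))
        counts = pyr.n_per_scale
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestStructureFunctions:
    def test_q_zero_gives_exactly_one(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(1024), 4))
        sf = structure_functions(pyr, [0.0])
        np.testing.assert_array_equal(sf.values[0], 1.0)

    def test_constant_leaders_give_c_to_the_q(self):
        pyr = constant_leader_pyramid([2.5] * 3, [64, 32, 16])
        sf = structure_functions(pyr, [-2, 0, 1, 3])
        for qi, q in enumerate([-2, 0, 1, 3]):
            np.testing.assert_allclose(sf.values[qi], 2.5**q, rtol=1e-12)

    def test_matches_naive_summation(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(256), 3))
        q_grid = [-3.0, -1.0, 0.5, 2.0, 4.0]
        sf = structure_functions(pyr, q_grid)
        for j in range(1, 4):
            lead, v = pyr.leaders[j - 1], pyr.leader_valid[j - 1]
            for qi, q in enumerate(q_grid):
                naive = sum(lead[k] ** q for k in np.flatnonzero(v)) / v.sum()
                assert sf.values[qi, j - 1] == pytest.approx(naive, rel=1e-12)

    def test_near_zero_leader_invalidates_negative_q(self):
        pyr = compute_leaders(dwt_pyramid(np.zeros(512), 3))
        sf = structure_functions(pyr, [-1.0])
        assert not sf.negative_q_valid


class TestZeta:
    def test_exact_log_linear_input(self):
        q = np.array([-5.0, -1.0, 0.0, 2.0, 5.0])
        scales = np.arange(1, 6)
        values = 2.0 ** (scales[None, :] * q[:, None] * 0.6)
        sf = StructureFunctions(
            q_grid=q, values=values, scales=scales,
            negative_q_valid=np.array(True),
        )
        zeta = zeta_estimates(sf, 1, 5)
        np.testing.assert_allclose(zeta, 0.6 * q, atol=1e-12)
        assert zeta[2] == 0.0  # zeta(0) = 0 exactly

    def test_fbm_zeta_two_is_two_h(self):
        vals = []
        for seed in range(3):
            pyr = compute_leaders(dwt_pyramid(simulate_fbm(0.7, 2**16, seed), 7))
            zeta = zeta_estimates(structure_functions(pyr, [2.0]), 3, 7)
            vals.append(zeta[0])
        assert np.mean(vals) == pytest.approx(1.4, abs=0.15)

    def test_mrw_zeta_concave(self):
        # c2 < 0 bends zeta: zeta(4) - 2 zeta(2) = 4 c2 + O(c3) < 0
        gaps = []
        for seed in range(3):
            pyr = compute_leaders(dwt_pyramid(simulate_mrw(0.72, 0.08, 2**16, seed), 7))
            zeta = zeta_estimates(structure_functions(pyr, [2.0, 4.0]), 3, 7)
            gaps.append(zeta[1] - 2 * zeta[0])
        assert np.mean(gaps) < -0.1

    def test_requires_two_scales(self):
        pyr = compute_leaders(dwt_pyramid(np.random.default_rng(0).standard_normal(512), 3))
        sf = structure_functions(pyr, [1.0])
        with pytest.raises(ParameterError):
            zeta_estimates(sf, 2, 2)


class TestLogCumulants:
    def test_degenerate_leaders_exact(self):
        # L(j,k) = 2^{0.4 j}: c1 = 0.4 exactly, c2 = 0 exactly
        pyr = constant_leader_pyramid(
            [2.0 ** (0.4 * j) for j in (1, 2, 3)], [64, 32, 16]
        )
        c1, c2 = log_cumulants(pyr, 1, 3)
        assert c1 == pytest.approx(0.4, abs=1e-12)
        assert c2 == pytest.approx(0.0, abs=1e-12)

    def test_too_few_leaders_flags_invalid(self):
        pyr = constant_leader_pyramid([1.0, 1.0, 1.0], [64, 32, 4])
        c1, c2 = log_cumulants(pyr, 1, 3)
        assert np.isnan(c1) and np.isnan(c2)

    def test_fbm_recovery(self):
        c1s, c2s = [], []
        for seed in range(5):
            pyr = compute_leaders(dwt_pyramid(simulate_fbm(0.7, 2**16, seed), 7))
            c1, c2 = log_cumulants(pyr, 3, 7)
            c1s.append(c1)
            c2s.append(c2)
        assert np.mean(c1s) == pytest.approx(0.7, abs=0.05)
        assert abs(np.mean(c2s)) < 0.02


class TestBootstrap:
    def test_identity_resample_equals_plug_in(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(2048), 5))
        est = bootstrap_cumulants(pyr, 2, 5, R=1, seed=0, identity_resample=True)
        c1, c2 = log_cumulants(pyr, 2, 5)
        assert est.c1 == pytest.approx(c1, abs=1e-12)
        assert est.c2 == pytest.approx(c2, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(2048), 5))
        a = bootstrap_cumulants(pyr, 2, 5, R=20, seed=11)
        b = bootstrap_cumulants(pyr, 2, 5, R=20, seed=11)
        np.testing.assert_array_equal(a.bootstrap_c1, b.bootstrap_c1)
        assert a.c1 == b.c1 and a.c2 == b.c2

    def test_reported_value_is_bootstrap_mean_with_r_replicates(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(4096), 5))
        est = bootstrap_cumulants(pyr, 2, 5, R=40, seed=3)
        assert est.bootstrap_c1.shape[-1] == 40
        assert est.c1 == pytest.approx(est.bootstrap_c1.mean(), abs=1e-14)
        assert est.c2 == pytest.approx(est.bootstrap_c2.mean(), abs=1e-14)

    def test_bootstrap_mean_consistent_with_plug_in(self):
        pyr = compute_leaders(dwt_pyramid(simulate_fbm(0.6, 2**15, seed=4), 7))
        est = bootstrap_cumulants(pyr, 3, 7, R=100, seed=5)
        c1, _ = log_cumulants(pyr, 3, 7)
        assert abs(est.c1 - c1) <= 2.0 * est.bootstrap_c1.std()

    def test_r_must_be_positive(self, rng):
        pyr = compute_leaders(dwt_pyramid(rng.standard_normal(1024), 4))
        with pytest.raises(ParameterError):
            bootstrap_cumulants(pyr, 2, 4, R=0)
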