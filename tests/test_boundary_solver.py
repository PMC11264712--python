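"""Optimal-stopping solver: preposterior algebra, Bellman recursion,
boundary structure and design-selection thresholds."""

import math

import numpy as np
import pytest
from scipy import stats

from vbseq.boundary_solver import (DPConfig, StoppingBoundary,
                                   bellman_residuals, classify_prior,
                                   expected_stop_value, fixed_policy_values,
                                   one_stage_enbs, preposterior_sd,
                                   simulate_policy_value, solve_boundary)
from vbseq.econ_core import DesignParams, PriorSpec


class TestPreposteriorSd:
    def test_no_new_information(self, prior):
        assert preposterior_sd(10, 0, prior) == 0.0

    def test_vanishes_at_large_n(self, prior):
        assert preposterior_sd(10 ** 9, 74, prior) < 0.01

    def test_monte_carlo_oracle(self, prior, rng):
        """SD of the updated posterior mean over simulated data batches."""
        n, m = 20, 74
        reps = 300_000
        post_sd = prior.sigma_X / math.sqrt(prior.n0 + n)
        mu_start = -200.0
        mu_true = rng.normal(mu_start, post_sd, size=reps)
        batch_sums = rng.normal(mu_true * m, prior.sigma_X * math.sqrt(m))
        mu_updated = ((prior.n0 + n) * mu_start + batch_sums) / (prior.n0 + n + m)
        mc = mu_updated.std(ddof=1)
        assert preposterior_sd(n, m, prior) == pytest.approx(mc, rel=0.01)


class TestExpectedStopValue:
    def test_degenerate_predictive(self, params, prior):
        mu = params.I / params.P + 100.0
        assert expected_stop_value(mu, 5, 0, params, prior) == \
            pytest.approx(params.P * mu - params.I)

    def test_symmetric_case_closed_form(self, params, prior):
        mu = params.I / params.P
        s = preposterior_sd(20, 74, prior)
        assert expected_stop_value(mu, 20, 74, params, prior) == \
            pytest.approx(params.P * s * stats.norm.pdf(0.0))

    def test_monte_carlo_oracle(self, params, prior, rng):
        s = preposterior_sd(20, 74, prior)
        draws = rng.normal(0.0, s, size=1_000_000)
        mc = np.maximum(params.P * draws - params.I, 0.0).mean()
        assert expected_stop_value(0.0, 20, 74, params, prior) == \
            pytest.approx(mc, rel=0.005)


class TestSolveBoundary:
    def test_boundary_structure(self, boundary124):
        bd = boundary124
        n = bd.n_grid
        assert n[0] == 1 and n[-1] == bd.params.T_max - bd.params.tau
        assert np.all(bd.upper[1:] >= bd.lower[1:])
        # mirror symmetry at I=0, within a grid step
        finite = np.isfinite(bd.upper)
        assert np.allclose(bd.upper[finite], -bd.lower[finite],
                           atol=bd.dp.mu_grid_step)

    def test_bellman_consistency(self, boundary124):
        res = bellman_residuals(boundary124)
        assert float(res.max()) < boundary124.dp.tolerance

    def test_prohibitive_sampling_cost_empty_continuation(self, params, prior):
        bd = solve_boundary(params.with_(c=1e9), prior, thresholds=False)
        kink = params.I / params.P
        assert np.allclose(bd.upper[1:], kink)
        assert np.allclose(bd.lower[1:], kink)

    def test_grid_convergence(self, params, prior, boundary124):
        fine = solve_boundary(params, prior, DPConfig(mu_grid_step=25.0),
                              thresholds=False)
        for n in range(1, boundary124.n_last):
            assert abs(fine.upper[n] - boundary124.upper[n]) < 100.0

    def test_value_monotone_in_cost_and_population(self, params, prior):
        dp = DPConfig(mu_grid_step=100.0, mu_grid_half_width=40_000.0)
        base = solve_boundary(params, prior, dp, thresholds=False)
        dearer = solve_boundary(params.with_(c=3_000.0), prior, dp,
                                thresholds=False)
        bigger = solve_boundary(params.with_(P=40_000.0), prior, dp,
                                thresholds=False)
        assert np.all(dearer.root_value <= base.root_value + 1e-6)
        assert np.all(bigger.root_value >= base.root_value - 1e-6)

    def test_policy_evaluation_matches_dp_root(self, boundary124, rng):
        """MC value of following the boundary equals V(0, mu0), and no
        fixed stopping time beats it."""
        bd = boundary124
        centre = int(np.argmin(np.abs(bd.mu_grid - bd.prior.mu0)))
        v_root = bd.root_value[centre]
        vals = simulate_policy_value(bd, 40_000, rng)
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert vals.mean() == pytest.approx(v_root, abs=3 * se)
        fixed = fixed_policy_values(bd, np.arange(0, bd.n_last + 1, 5))
        assert vals.mean() >= fixed.max() - 3 * se

    def test_save_load_round_trip(self, boundary124, tmp_path, params, prior):
        path = tmp_path / "bd.csv"
        boundary124.save(path)
        back = StoppingBoundary.load(path, params, prior)
        assert np.allclose(back.upper, boundary124.upper)
        assert back.A == pytest.approx(boundary124.A)
        for n in (10, 30, 49):
            assert back.crossed(n, boundary124.upper[n] + 1.0)
            assert not back.crossed(n, 0.0)


class TestOneStageEnbs:
    def test_zero_sample_size_zero_gain(self, params, prior):
        assert one_stage_enbs(0, 1_000.0, params, prior) == pytest.approx(0.0)

    def test_unimodal_in_n(self, params, prior):
        curve = np.array([one_stage_enbs(n, 0.0, params, prior)
                          for n in range(1, 501)])
        k = int(curve.argmax())
        assert np.all(np.diff(curve[:k + 1]) > 0)
        assert np.all(np.diff(curve[k:]) < 0)

    def test_negative_beyond_no_trial_point(self, params, prior, boundary124):
        mu0 = boundary124.A + 2_000.0
        curve = [one_stage_enbs(n, mu0, params, prior) for n in range(1, 301)]
        assert max(curve) < 0.0


class TestDesignSelection:
    def test_threshold_ordering_and_symmetry(self, boundary124):
        bd = boundary124
        assert bd.B < bd.D < 0 < bd.C < bd.A
        assert bd.A == pytest.approx(-bd.B, rel=1e-6)
        assert bd.C == pytest.approx(-bd.D, rel=1e-6)

    @pytest.mark.parametrize("mu0, expected", [
        (0.0, "sequential"),
        (20_000.0, "no_trial_adopt_N"),
        (-20_000.0, "no_trial_keep_S"),
        (14_000.0, "one_stage"),
        (-14_000.0, "one_stage"),
    ])
    def test_classification(self, boundary124, mu0, expected):
        assert classify_prior(mu0, boundary124) == expected
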