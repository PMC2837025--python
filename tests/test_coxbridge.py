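import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathpower._kernels import prox_bridge
from pathpower.coxbridge import (
    CoxSample,
    default_lambda_grid,
    fit_bridge_cox,
    fit_bridge_path,
    lambda_max,
    neg_log_partial_likelihood,
    risk_score,
    select_lambda_cv,
)

from conftest import make_cox_data


def lifelines_fit(x, t, d):
    import pandas as pd
    from lifelines import CoxPHFitter

    df = pd.DataFrame(x, columns=[f"x{j}" for j in range(x.shape[1])])
    df["T"], df["E"] = t, d
    cph = CoxPHFitter()
    cph.fit(df, "T", "E")
    return cph


class TestNegLogPartialLikelihood:
    def test_three_subjects_at_null(self):
        # at beta = 0 each death contributes log(risk-set size)
        data = CoxSample(np.zeros((3, 1)), [3.0, 2.0, 1.0], [1, 1, 1])
        expected = (math.log(3) + math.log(2) + math.log(1)) / 3
        assert neg_log_partial_likelihood(np.zeros(1), data) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(0.5973, abs=1e-4)

    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_log_factorial_at_null(self, n, rng):
        data = CoxSample(
            rng.normal(size=(n, 3)), np.arange(1, n + 1, dtype=float), np.ones(n)
        )
        assert neg_log_partial_likelihood(np.zeros(3), data) == pytest.approx(
            math.log(math.factorial(n)) / n
        )

    def test_matches_reference_loglik(self):
        x, t, d = make_cox_data(80, 3, [0.5, -0.3, 0.0], seed=3)
        data = CoxSample(x, t, d)
        cph = lifelines_fit(x, t, d)
        beta = cph.params_.values
        ours = -80 * neg_log_partial_likelihood(beta, data)
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-8)

    def test_separating_covariate_monotone(self):
        # covariate perfectly orders the event times: likelihood keeps
        # improving as |beta| grows
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        data = CoxSample(x, [4.0, 3.0, 2.0, 1.0], [1, 1, 1, 1])
        vals = [neg_log_partial_likelihood(np.array([b]), data)
                for b in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) < 0)

    def test_nonfinite_covariates_error(self):
        with pytest.raises(ValueError):
            CoxSample(np.array([[np.inf]]), [1.0], [1])


class TestFitBridge:
    def test_lambda_zero_matches_reference(self):
        for seed, m in [(0, 2), (1, 4), (2, 5)]:
            beta_true = np.zeros(m)
            beta_true[:2] = [0.8, -0.5]
            x, t, d = make_cox_data(200, m, beta_true, seed=seed)
            data = CoxSample(x, t, d)
            fit = fit_bridge_cox(data, 0.0)
            ref = lifelines_fit(x, t, d).params_.values
            assert fit.converged
            np.testing.assert_allclose(fit.beta, ref, atol=1e-4)

    def test_full_shrinkage_at_lambda_max(self):
        x, t, d = make_cox_data(150, 4, [1.0, 0, 0, 0], seed=5)
        data = CoxSample(x, t, d)
        lmax = lambda_max(data)
        fit = fit_bridge_cox(data, lmax)
        np.testing.assert_array_equal(fit.beta, 0.0)
        assert fit.selected.size == 0
        below = fit_bridge_cox(data, 0.95 * lmax)
        assert below.selected.size >= 1

    def test_single_gene_consistency(self):
        # true beta = 1, n = 500: estimate within 3 SE of the truth
        x, t, d = make_cox_data(500, 1, [1.0], seed=11)
        data = CoxSample(x, t, d)
        fit = fit_bridge_cox(data, lam=0.001)
        se = lifelines_fit(x, t, d).standard_errors_.values[0]
        assert abs(fit.beta[0] - 1.0) < 3 * se

    def test_covariate_scaling_equivariance(self):
        x, t, d = make_cox_data(200, 3, [0.5, -0.5, 0.0], seed=9)
        f1 = fit_bridge_cox(CoxSample(x, t, d), 0.0)
        f2 = fit_bridge_cox(CoxSample(4.0 * x, t, d), 0.0)
        np.testing.assert_allclose(f2.beta, f1.beta / 4.0, atol=1e-5)

    def test_selected_indexes_nonzeros(self):
        x, t, d = make_cox_data(150, 5, [1.2, 0, 0, 0, 0], seed=13)
        data = CoxSample(x, t, d)
        fit = fit_bridge_cox(data, 0.3 * lambda_max(data))
        np.testing.assert_array_equal(fit.selected, np.flatnonzero(fit.beta))

    def test_warm_path_objective_dominates_cold_refit(self):
        x, t, d = make_cox_data(120, 4, [0.7, -0.7, 0, 0], seed=21)
        data = CoxSample(x, t, d)
        grid = default_lambda_grid(data, n_points=6)
        betas = fit_bridge_path(data, grid)

        def penalized(beta, lam):
            return neg_log_partial_likelihood(beta, data) + lam * np.sum(
                np.abs(beta) ** 0.5
            )

        for k in range(1, len(grid)):
            # warm-started solution is no worse at lam_k than the
            # previous path point evaluated there
            assert penalized(betas[k], grid[k]) <= penalized(
                betas[k - 1], grid[k]
            ) + 1e-9


class TestProxBridge:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        z=st.floats(-5, 5),
        a=st.floats(0.05, 5),
        lam=st.floats(0, 2),
        gamma=st.sampled_from([0.3, 0.5, 0.7]),
    )
    def test_scalar_global_minimum(self, z, a, lam, gamma):
        b = prox_bridge(z, a, lam, gamma)

        def f(v):
            return 0.5 * a * (v - z) ** 2 + lam * np.abs(v) ** gamma

        grid = np.linspace(-abs(z) - 1, abs(z) + 1, 4001)
        assert f(b) <= f(grid).min() + 1e-6


class TestSelectLambdaCV:
    def test_singleton_grid(self):
        x, t, d = make_cox_data(60, 2, [0, 0], seed=1)
        assert select_lambda_cv(CoxSample(x, t, d), [0.37]) == 0.37

    def test_pure_noise_prefers_heavy_penalty(self):
        hits = 0
        for seed in range(20):
            x, t, d = make_cox_data(100, 5, np.zeros(5), seed=100 + seed)
            data = CoxSample(x, t, d)
            grid = default_lambda_grid(data, n_points=8)
            lam = select_lambda_cv(data, grid, seed=seed)
            if lam >= grid[1]:  # at or adjacent to the largest value
                hits += 1
        assert hits > 10

    def test_signal_keeps_true_gene(self):
        hits = 0
        for seed in range(10):
            x, t, d = make_cox_data(150, 4, [1.5, 0, 0, 0], seed=200 + seed)
            data = CoxSample(x, t, d)
            grid = default_lambda_grid(data, n_points=8)
            lam = select_lambda_cv(data, grid, seed=seed)
            if fit_bridge_cox(data, lam).beta[0] != 0:
                hits += 1
        assert hits > 5

    def test_deterministic_given_seed(self):
        x, t, d = make_cox_data(90, 3, [0.5, 0, 0], seed=17)
        data = CoxSample(x, t, d)
        grid = default_lambda_grid(data, n_points=6)
        assert select_lambda_cv(data, grid, seed=5) == select_lambda_cv(
            data, grid, seed=5
        )


class TestRiskScore:
    def test_linear_algebra(self):
        assert risk_score(np.array([1.0, 0.0]), np.array([[3.0, 7.0]]))[0] == 3.0
        np.testing.assert_array_equal(
            risk_score(np.zeros(2), np.ones((4, 2))), np.zeros(4)
        )

    def test_gene_permutation_invariance(self, rng):
        beta = rng.normal(size=5)
        x = rng.normal(size=(10, 5))
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            risk_score(beta, x), risk_score(beta[perm], x[:, perm])
        )
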