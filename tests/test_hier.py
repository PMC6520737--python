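import numpy as np
import pytest

from ieinter import (
    HierarchicalInteractionLasso,
    MainEffectsLasso,
    PenaltyConfig,
    ebic_score,
    fit_hier_lasso,
    fit_main_only_lasso,
    predict_joint,
    tune,
)


def cd_lasso_unpenalized_E(y, E, X, lam, tol=1e-13, max_iter=20000):
    """Coordinate descent for min ||y - E tau - X eta||^2 + lam * sum|eta|.

    Independent oracle: plain cyclic coordinate updates, soft threshold
    on the penalized block only.
    """
    n, J = E.shape
    K = X.shape[1]
    tau, eta = np.zeros(J), np.zeros(K)
    r = y.copy()
    eE = (E**2).sum(axis=0)
    eX = (X**2).sum(axis=0)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(J):
            old = tau[j]
            tau[j] = old + E[:, j] @ r / eE[j]
            r -= (tau[j] - old) * E[:, j]
            delta = max(delta, abs(tau[j] - old))
        for k in range(K):
            old = eta[k]
            rho = X[:, k] @ r + eX[k] * old
            new = np.sign(rho) * max(abs(rho) - lam / 2, 0.0) / eX[k]
            eta[k] = new
            r -= (new - old) * X[:, k]
            delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return tau, eta


def random_problem(rng, n=60, K=12, J=3, snr=1.0):
    E = rng.standard_normal((n, J))
    X = rng.standard_normal((n, K))
    beta = np.zeros(K)
    beta[: K // 3] = rng.standard_normal(K // 3)
    y = E @ rng.standard_normal(J) * 0.5 + X @ beta + rng.standard_normal(n) / snr
    return y - y.mean(), E - E.mean(axis=0), X - X.mean(axis=0)


class TestPredictJoint:
    def test_null_model_predicts_outcome_mean(self, rng):
        n, J, K = 30, 2, 5
        E, X = rng.standard_normal((n, J)), rng.standard_normal((n, K))
        y = rng.standard_normal(n) + 3.0
        m = HierarchicalInteractionLasso(lambda1=1e9, lambda2=np.inf).fit(X, y, E=E)
        # tau is unpenalized, so zero it to probe the pure intercept
        m.tau_ = np.zeros(J)
        np.testing.assert_allclose(m.predict(X, E=E), np.full(n, y.mean()), atol=1e-10)

    def test_single_clinical_term(self, rng):
        n = 25
        E, X = rng.standard_normal((n, 2)), rng.standard_normal((n, 3))
        y = np.zeros(n)
        m = HierarchicalInteractionLasso(lambda1=1.0, lambda2=1.0, standardize=False).fit(
            X - X.mean(axis=0), y, E=E - E.mean(axis=0)
        )
        m.tau_ = np.array([1.0, 0.0])
        m.eta_ = np.zeros(3)
        m.theta_ = np.zeros((2, 3))
        Ec = E - E.mean(axis=0)
        np.testing.assert_allclose(
            m.predict(X - X.mean(axis=0), E=Ec), Ec[:, 0], atol=1e-12
        )

    def test_matches_term_by_term_summation(self, rng):
        n, J, K = 15, 3, 4
        E, X = rng.standard_normal((n, J)), rng.standard_normal((n, K))
        m = HierarchicalInteractionLasso(lambda1=1.0, lambda2=1.0, standardize=False).fit(
            X, rng.standard_normal(n), E=E
        )
        m.tau_ = rng.standard_normal(J)
        m.eta_ = rng.standard_normal(K)
        m.theta_ = rng.standard_normal((J, K))
        pred = predict_joint(m, E - m.e_means_ + m.e_means_, X)
        expected = np.full(n, m.y_mean_)
        Ec, Xc = E - m.e_means_, (X - m.x_means_) / m.x_scales_
        for i in range(n):
            for j in range(J):
                expected[i] += m.tau_[j] * Ec[i, j]
            for k in range(K):
                expected[i] += m.eta_[k] * Xc[i, k]
                for j in range(J):
                    expected[i] += m.eta_[k] * m.theta_[j, k] * Ec[i, j] * Xc[i, k]
        np.testing.assert_allclose(pred, expected, atol=1e-10)


class TestHierLasso:
    def test_full_shrinkage_limit_is_clinical_ols(self, rng):
        y, E, X = random_problem(rng)
        m = fit_hier_lasso(y, E, X, PenaltyConfig(lambda1=1e8, lambda2=1e8))
        assert not m.eta_.any() and not m.theta_.any()
        np.testing.assert_allclose(
            m.tau_, np.linalg.lstsq(E, y, rcond=None)[0], atol=1e-8
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_lambda2_inf_matches_cd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, E, X = random_problem(rng, n=50, K=15, J=2)
        lam = 0.3 * 2 * np.abs(X.T @ y).max()
        m = fit_hier_lasso(
            y, E, X, PenaltyConfig(lambda1=lam, lambda2=np.inf, solver_tol=1e-12)
        )
        tau, eta = cd_lasso_unpenalized_E(y, E, X, lam)
        np.testing.assert_allclose(m.eta_, eta, atol=1e-8)
        np.testing.assert_allclose(m.tau_, tau, atol=1e-8)

    def test_noise_free_sparse_recovery(self):
        rng = np.random.default_rng(99)
        n, K, J = 500, 50, 4
        E = rng.standard_normal((n, J))
        X = rng.standard_normal((n, K))
        E -= E.mean(axis=0)
        X -= X.mean(axis=0)
        tau = np.array([0.5, -0.4, 0.3, 0.0])
        eta = np.zeros(K)
        eta[[3, 10, 25]] = [1.0, -1.5, 0.8]
        theta = np.zeros((J, K))
        theta[0, 3] = 0.9
        theta[2, 10] = -0.6
        f = E @ tau + X @ eta + ((E @ theta) * X) @ eta
        m = fit_hier_lasso(
            f, E, X, PenaltyConfig(lambda1=0.05, lambda2=0.05, solver_tol=1e-13, tol=1e-10)
        )
        # support up to the numerical floor of the small-penalty solution;
        # coefficient accuracy is bounded by the honest lasso shrinkage
        # bias of the product objective (validated against a direct
        # minimiser of the restricted problem)
        assert set(np.flatnonzero(np.abs(m.eta_) > 1e-2)) == {3, 10, 25}
        np.testing.assert_allclose(m.eta_[[3, 10, 25]], [1.0, -1.5, 0.8], atol=2e-3)
        np.testing.assert_allclose(m.tau_, tau, atol=2e-3)
        gamma_true = eta[None, :] * theta
        np.testing.assert_allclose(m.gamma_, gamma_true, atol=1e-2)

    def test_objective_monotone_nonincreasing(self, rng):
        y, E, X = random_problem(rng, n=80, K=20)
        lam1 = 0.1 * 2 * np.abs(X.T @ y).max()
        m = fit_hier_lasso(y, E, X, PenaltyConfig(lambda1=lam1, lambda2=lam1 / 4))
        diffs = np.diff(m.objective_path_)
        assert np.all(diffs <= 1e-8 * max(1.0, m.objective_path_[0]))

    def test_hierarchy_invariant_on_tuned_fit(self, continuous_dataset):
        from ieinter import fit_joint

        m = fit_joint(continuous_dataset, PenaltyConfig(n_lambda1=10, n_lambda2=6))
        violations = m.gamma_[:, m.eta_ == 0]
        assert not violations.any()

    def test_feature_permutation_equivariance(self, rng):
        y, E, X = random_problem(rng, n=60, K=10)
        lam1 = 0.2 * 2 * np.abs(X.T @ y).max()
        config = PenaltyConfig(lambda1=lam1, lambda2=lam1 / 2, solver_tol=1e-12, tol=1e-12)
        m1 = fit_hier_lasso(y, E, X, config)
        perm = rng.permutation(X.shape[1])
        m2 = fit_hier_lasso(y, E, X[:, perm], config)
        np.testing.assert_allclose(m2.eta_, m1.eta_[perm], atol=1e-6)
        np.testing.assert_allclose(m2.theta_, m1.theta_[:, perm], atol=1e-6)

    def test_predictions_invariant_to_feature_scale(self, rng):
        y, E, X = random_problem(rng, n=60, K=8)
        scales = rng.uniform(0.5, 10.0, X.shape[1])
        m1 = HierarchicalInteractionLasso(lambda1=2.0, lambda2=1.0).fit(X, y, E=E)
        m2 = HierarchicalInteractionLasso(lambda1=2.0, lambda2=1.0).fit(
            X * scales, y, E=E
        )
        np.testing.assert_allclose(
            m1.predict(X, E=E), m2.predict(X * scales, E=E), atol=1e-6
        )

    def test_same_input_same_output_determinism(self, rng):
        y, E, X = random_problem(rng, n=50, K=10)
        m1 = HierarchicalInteractionLasso(n_lambda1=6, n_lambda2=4).fit(X, y, E=E)
        m2 = HierarchicalInteractionLasso(n_lambda1=6, n_lambda2=4).fit(X, y, E=E)
        assert m1.lambda1_ == m2.lambda1_ and m1.lambda2_ == m2.lambda2_
        np.testing.assert_array_equal(m1.eta_, m2.eta_)
        np.testing.assert_array_equal(m1.theta_, m2.theta_)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(lambda1=-1.0)


class TestEbic:
    def test_hand_evaluation(self):
        assert ebic_score(100, 100, 3, 1000, 0.5) == pytest.approx(34.539, abs=1e-3)

    def test_gamma_zero_is_classical_bic(self):
        rss, n, df, p = 57.0, 80, 5, 400
        assert ebic_score(rss, n, df, p, 0.0) == pytest.approx(
            n * np.log(rss / n) + df * np.log(n)
        )

    def test_monotone_in_df(self):
        scores = [ebic_score(50, 100, df, 500, 0.5) for df in range(6)]
        assert np.all(np.diff(scores) > 0)

    def test_zero_rss_guarded(self):
        with pytest.warns(RuntimeWarning):
            val = ebic_score(0.0, 50, 2, 100, 0.5)
        assert np.isfinite(val)


class TestTuning:
    def test_ebic_path_records_grid(self, rng):
        y, E, X = random_problem(rng, n=50, K=10)
        model, path = tune(y, E, X, PenaltyConfig(n_lambda1=5, n_lambda2=3))
        assert {"lambda1", "lambda2", "df", "rss", "ebic"} <= set(path.columns)
        assert model.ebic_ == pytest.approx(path["ebic"].min(), rel=1e-9)

    def test_warm_start_equals_cold_restart_selection(self, rng):
        """The tuned model is reproducible via a direct fixed-lambda refit."""
        y, E, X = random_problem(rng, n=60, K=12)
        model, _ = tune(y, E, X, PenaltyConfig(n_lambda1=6, n_lambda2=4))
        refit = fit_hier_lasso(
            y, E, X, PenaltyConfig(lambda1=model.lambda1_, lambda2=model.lambda2_)
        )
        assert set(np.flatnonzero(refit.eta_)) == set(np.flatnonzero(model.eta_))


class TestMainOnlyLasso:
    def test_zero_penalty_is_ols(self, rng):
        n, K, J = 60, 8, 2
        E, X = rng.standard_normal((n, J)), rng.standard_normal((n, K))
        y = rng.standard_normal(n)
        E -= E.mean(axis=0)
        X -= X.mean(axis=0)
        y = y - y.mean()
        m = fit_main_only_lasso(y, E, X, lam=0.0)
        D = np.column_stack([E, X])
        coef = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(m.tau_, coef[:J], atol=1e-8)
        np.testing.assert_allclose(m.eta_, coef[J:], atol=1e-8)

    def test_large_penalty_gives_clinical_only_model(self, rng):
        y, E, X = random_problem(rng)
        m = fit_main_only_lasso(y, E, X, lam=1e9)
        assert not m.eta_.any()

    def test_equals_hier_lasso_at_lambda2_inf(self, rng):
        y, E, X = random_problem(rng, n=70, K=14)
        lam = 0.2 * 2 * np.abs(X.T @ y).max()
        a = fit_main_only_lasso(y, E, X, lam=lam)
        b = fit_hier_lasso(y, E, X, PenaltyConfig(lambda1=lam, lambda2=np.inf))
        np.testing.assert_allclose(a.eta_, b.eta_, atol=1e-10)
        assert not b.theta_.any()
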