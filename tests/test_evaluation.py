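import numpy as np
import pytest
from scipy import stats

from ieinter import (
    pmse_resampling,
    risk_stratify_logrank,
    rv_coefficient,
    selection_overlap,
)


def logrank_oev(times, status, group):
    """Logrank statistic by explicit O/E/V tabulation over event times.

    Independent oracle: at each distinct event time t, with n1, n at
    risk and d events (d1 in group 1), accumulate O - E = d1 - d*n1/n
    and hypergeometric variance d*(n1/n)*(1-n1/n)*(n-d)/(n-1).
    """
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[status == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (status == 1)).sum()
        d1 = ((times == t) & (status == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestRiskStratifyLogrank:
    def test_identical_groups_statistic_zero(self):
        # two groups with identical event patterns
        times = [1, 2, 3, 1, 2, 3]
        status = [1, 1, 0, 1, 1, 0]
        pred = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
        stat, p, labels = risk_stratify_logrank(pred, times, status)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_under_label_swap(self, rng):
        n = 20
        times = rng.exponential(2, n) + 0.1
        status = (rng.random(n) < 0.7).astype(int)
        pred = rng.standard_normal(n)
        s1, _, _ = risk_stratify_logrank(pred, times, status)
        s2, _, _ = risk_stratify_logrank(-pred, times, status)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_matches_oev_tabulation_oracle(self):
        times = np.array([2.0, 3.0, 4.0, 5.0, 7.0, 9.0])
        status = np.array([1, 1, 0, 1, 1, 1])
        pred = np.array([0.1, 0.2, 0.9, 0.8, 0.95, 0.3])
        stat, p, labels = risk_stratify_logrank(pred, times, status)
        group = (labels == "low").astype(int)
        expected = logrank_oev(times, status, group)
        assert stat == pytest.approx(expected, rel=1e-9)

    def test_pvalue_is_chi2_tail(self, rng):
        n = 30
        times = rng.exponential(2, n) + 0.1
        status = (rng.random(n) < 0.8).astype(int)
        pred = rng.standard_normal(n)
        stat, p, _ = risk_stratify_logrank(pred, times, status)
        assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)

    def test_median_ties_go_high_risk(self):
        pred = [1.0, 1.0, 1.0, 2.0]
        _, _, labels = risk_stratify_logrank(pred, [1, 2, 3, 4], [1, 1, 1, 1])
        assert list(labels) == ["high", "high", "high", "low"]

    def test_constant_predictions_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            risk_stratify_logrank([1.0] * 6, [1, 2, 3, 4, 5, 6], [1] * 6)


class TestRVCoefficient:
    def test_self_similarity_is_one(self, rng):
        A = rng.standard_normal((10, 3))
        assert rv_coefficient(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_single_columns_zero(self):
        a = np.array([[1.0], [-1.0], [0.0], [0.0]])
        b = np.array([[0.0], [0.0], [1.0], [-1.0]])
        assert rv_coefficient(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_trace_formula(self):
        A = np.array([[1.0, 0.5], [-1, 0.2], [0.3, -0.9], [-0.3, 0.2]])
        B = np.array([[0.2, 1.0], [0.1, -1], [-0.5, 0.4], [0.2, -0.4]])
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        SA, SB = Ac @ Ac.T, Bc @ Bc.T
        expected = np.trace(SA @ SB) / np.sqrt(np.trace(SA @ SA) * np.trace(SB @ SB))
        assert rv_coefficient(A, B) == pytest.approx(expected, rel=1e-12)

    def test_rotation_and_scale_invariance(self, rng):
        A = rng.standard_normal((12, 4))
        B = rng.standard_normal((12, 3))
        base = rv_coefficient(A, B)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert rv_coefficient(A @ Q, B) == pytest.approx(base, rel=1e-9)
        assert rv_coefficient(A * 7.3, B / 2.1) == pytest.approx(base, rel=1e-9)

    def test_bounds(self, rng):
        for _ in range(20):
            v = rv_coefficient(rng.standard_normal((8, 3)), rng.standard_normal((8, 5)))
            assert -1e-12 <= v <= 1 + 1e-12

    def test_zero_matrix_undefined(self, rng):
        with pytest.raises(ValueError):
            rv_coefficient(np.zeros((5, 2)), rng.standard_normal((5, 2)))


class TestSelectionOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (["f1", "f2", "f3"], ["f3", "f4"], (3, 2, 1)),
            (list(range(8)), list(range(8)), (8, 8, 8)),
            (["a"], ["b"], (1, 1, 0)),
        ],
    )
    def test_counting(self, a, b, expected):
        assert selection_overlap(a, b) == expected


class _OracleFitter:
    """Knows the generating function exactly."""

    def __init__(self, truth, x_means, e_means, y_mean):
        self.truth, self.x_means, self.e_means, self.y_mean = truth, x_means, e_means, y_mean

    def fit(self, ds):
        return self

    def predict(self, X, E=None):
        return self.truth.linear_predictor(E, X)


class _MeanFitter:
    def fit(self, ds):
        self.mean_ = float(ds.outcome.y.mean())
        return self

    def predict(self, X, E=None):
        return np.full(X.shape[0], self.mean_)


class TestPmseResampling:
    def test_perfect_predictor_has_zero_pmse(self, small_config, small_truth):
        from ieinter import ContinuousOutcome, Dataset, generate_design

        E, X = generate_design(small_config)
        y = small_truth.linear_predictor(E.values, X.values)  # noise-free
        ds = Dataset(E=E, X=X, outcome=ContinuousOutcome(y))
        oracle = _OracleFitter(small_truth, None, None, 0.0)
        rep = pmse_resampling(ds, {"oracle": lambda d: oracle.fit(d)}, n_rep=5, seed=3)
        assert rep.pmse_mean["oracle"] == pytest.approx(0.0, abs=1e-20)

    def test_mean_fitter_pmse_approximates_variance(self, rng):
        from ieinter import (
            ClinicalMatrix,
            ContinuousOutcome,
            Dataset,
            FeatureMatrix,
        )

        n = 2000
        y = rng.standard_normal(n) * 2.0
        ds = Dataset(
            E=ClinicalMatrix(rng.standard_normal((n, 2)), ["a", "b"]),
            X=FeatureMatrix(rng.standard_normal((n, 3)), ["f1", "f2", "f3"]),
            outcome=ContinuousOutcome(y),
        )
        rep = pmse_resampling(ds, {"mean": lambda d: _MeanFitter().fit(d)}, n_rep=10, seed=1)
        assert rep.pmse_mean["mean"] == pytest.approx(np.var(y), rel=0.1)

    def test_same_seed_bit_identical(self, continuous_dataset):
        fitters = {"mean": lambda d: _MeanFitter().fit(d)}
        r1 = pmse_resampling(continuous_dataset, fitters, n_rep=4, seed=9)
        r2 = pmse_resampling(continuous_dataset, fitters, n_rep=4, seed=9)
        assert r1.pmse_mean == r2.pmse_mean and r1.pmse_sd == r2.pmse_sd

    def test_interaction_model_predicts_no_worse_with_true_interactions(self):
        """With strong true interactions, the hierarchy-respecting model
        should not lose to the main-effects-only lasso in held-out PMSE."""
        import numpy as np

        from ieinter import (
            ContinuousOutcome,
            Dataset,
            PenaltyConfig,
            SyntheticConfig,
            TrueModel,
            fit_joint,
            generate_continuous,
            generate_design,
        )

        cfg = SyntheticConfig(
            n=120, group_sizes={"Texture": 12, "Geometry": 12, "Holistic": 6},
            rho=0.2, seed=21,
        )
        K = cfg.K
        eta = np.zeros(K)
        gamma = np.zeros((4, K))
        eta[[1, 14]] = [1.2, -1.0]
        gamma[0, 1] = 1.1
        gamma[3, 14] = -0.9
        truth = TrueModel(tau=np.array([0.4, 0, 0.3, 0]), eta=eta, gamma=gamma)
        E, X = generate_design(cfg)
        y = generate_continuous(E, X, truth, sigma=1.0, seed=22)
        ds = Dataset(E=E, X=X, outcome=y)
        grid = PenaltyConfig(n_lambda1=8, n_lambda2=6)
        fitters = {
            "interaction": lambda d: fit_joint(d, config=grid),
            "main_only": lambda d: fit_joint(d, config=grid, main_only=True),
        }
        rep = pmse_resampling(ds, fitters, n_rep=6, seed=23)
        assert rep.pmse_mean["interaction"] <= rep.pmse_mean["main_only"] * 1.05

    def test_survival_mode_reports_logrank(self, survival_dataset):
        class LogTimeMean:
            def fit(self, ds):
                self.v_ = np.log(ds.outcome.time).mean()
                return self

            def predict(self, X, E=None):
                # spread predictions so the median split is well defined
                return self.v_ + X[:, 0]

        rep = pmse_resampling(
            survival_dataset, {"lt": lambda d: LogTimeMean().fit(d)}, n_rep=4, seed=2
        )
        assert rep.n_effective["lt"] > 0
        assert rep.logrank_mean["lt"] >= 0
        assert 0 <= rep.logrank_mean_p["lt"] <= 1
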