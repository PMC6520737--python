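"""Joint interaction model: hierarchical lasso with product parameterization.

All clinical variables, all imaging features and all their pairwise
products enter one model,

    Y = sum_j tau_j E_j + sum_k eta_k X_k
        + sum_j sum_k eta_k * theta_jk E_j X_k + eps,

where the interaction coefficient is the product gamma_jk = eta_k *
theta_jk. Writing it as a product hard-wires the "main effects,
interactions" hierarchy: an interaction can be nonzero only when the
imaging main effect eta_k is. Estimation minimises

    ||Y - f(E, X)||^2 + lambda1 * sum_k |eta_k| + lambda2 * sum_jk |theta_jk|

with the low-dimensional clinical main effects tau unpenalized. The
nonconvex objective is attacked by deterministic block alternation:
with theta fixed the problem is a lasso in eta (on composite columns
X_k * (1 + sum_j theta_jk E_j)), and with eta fixed a lasso in theta
(on columns eta_k E_j X_k); tau is profiled out of both subproblems by
projecting onto the orthocomplement of the clinical design, so every
block update is an exact convex solve and the objective never
increases. Tuning parameters are chosen by the extended BIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso

from .data import Dataset, SurvivalOutcome, center_columns, standardize_columns
from .survival import km_weights, to_aft_scale

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyConfig",
    "HierarchicalInteractionLasso",
    "MainEffectsLasso",
    "ebic_score",
    "fit_hier_lasso",
    "fit_main_only_lasso",
    "tune",
    "predict_joint",
    "fit_joint",
]


@dataclass
class PenaltyConfig:
    """Penalty levels and tuning-grid controls for the joint model.

    ``lambda1``/``lambda2`` of None means "tune by EBIC over the grid";
    ``numpy.inf`` for ``lambda2`` freezes all interactions at zero.
    """

    lambda1: float | None = None
    lambda2: float | None = None
    n_lambda1: int = 20
    n_lambda2: int = 20
    lambda_min_ratio: float = 1e-3
    max_active: int | None = None
    ebic_gamma: float = 0.5
    tol: float = 1e-9
    max_iter: int = 200
    solver_tol: float = 1e-8

    def __post_init__(self) -> None:
        for lam in (self.lambda1, self.lambda2):
            if lam is not None and lam < 0:
                raise ValueError("penalty levels must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0 <= self.ebic_gamma <= 1:
            raise ValueError("ebic_gamma must be in [0, 1]")


def ebic_score(rss: float, n: int, df: int, p_total: int, ebic_gamma: float = 0.5) -> float:
    """Extended Bayesian information criterion for a squared-error fit.

    n * log(rss / n) + df * (log n + 2 * ebic_gamma * log p_total).
    At ebic_gamma = 0 this is the classical BIC; the extra term charges
    each degree of freedom for the log-size of the candidate model
    space, which keeps false discoveries down when p_total >> n.
    """
    if n <= 0 or df < 0 or p_total < 1:
        raise ValueError("need n > 0, df >= 0, p_total >= 1")
    floor = np.finfo(float).tiny
    if rss <= floor:
        warnings.warn("zero residual sum of squares in EBIC; flooring", RuntimeWarning)
        rss = floor
    return float(n * np.log(rss / n) + df * (np.log(n) + 2 * ebic_gamma * np.log(p_total)))


def _lasso(Z: np.ndarray, y: np.ndarray, lam: float, warm: np.ndarray | None = None,
           tol: float = 1e-8, max_iter: int = 20_000) -> np.ndarray:
    """min_b ||y - Z b||^2 + lam * sum|b|, no intercept."""
    n = len(y)
    if Z.shape[1] == 0:
        return np.zeros(0)
    if lam == 0:
        return np.linalg.lstsq(Z, y, rcond=None)[0]
    model = Lasso(alpha=lam / (2 * n), fit_intercept=False, max_iter=max_iter, tol=tol)
    if warm is not None:
        model.warm_start = True
        model.coef_ = np.asarray(warm, dtype=float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    return model.coef_.copy()


class _Projector:
    """Residual-maker for the unpenalized clinical block (I - P_E)."""

    def __init__(self, E: np.ndarray):
        self.E = E
        self.Q, self.R = np.linalg.qr(E)

    def __call__(self, M: np.ndarray) -> np.ndarray:
        return M - self.Q @ (self.Q.T @ M)

    def solve_tau(self, resid_target: np.ndarray) -> np.ndarray:
        """Least-squares clinical coefficients for a given (scaled) residual."""
        return np.linalg.lstsq(self.E, resid_target, rcond=None)[0]


def _alternate(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    lambda1: float,
    lambda2: float,
    tol: float,
    max_iter: int,
    eta0: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    proj: _Projector | None = None,
    solver_tol: float = 1e-8,
    s: np.ndarray | None = None,
    warn: bool = True,
) -> dict:
    """Block-alternating minimisation of the product-penalized objective.

    Works on centered/standardized arrays; ``s`` is an optional per-row
    scale (sqrt of the KM weights) so the loss is sum_i s_i^2 (y-f)_i^2.
    Design columns — including the E_j * X_k products — are always built
    from the unscaled data and only then row-scaled. Returns
    coefficients, the objective trace and convergence info.
    """
    n, K = X.shape
    J = E.shape[1]
    if s is None:
        s = np.ones(n)
    Es = s[:, None] * E
    ys = s * y
    proj = proj or _Projector(Es)
    Mys, MXs = proj(ys), proj(s[:, None] * X)

    eta = np.zeros(K) if eta0 is None else eta0.copy()
    theta = np.zeros((J, K)) if theta0 is None else theta0.copy()
    theta[:, eta == 0] = 0.0
    no_theta = np.isinf(lambda2)

    def objective(tau, eta, theta):
        f = E @ tau + X @ eta + ((E @ theta) * X) @ eta
        pen = lambda1 * np.abs(eta).sum()
        if not no_theta:
            pen += lambda2 * np.abs(theta).sum()
        return float(((s * (y - f)) ** 2).sum() + pen)

    obj_path: list[float] = []
    prev_coefs = None
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # eta step: lasso on composite columns, tau profiled out
        if no_theta or not theta.any():
            MZs = MXs
        else:
            MZs = proj(s[:, None] * (X * (1.0 + E @ theta)))
        eta = _lasso(MZs, Mys, lambda1, warm=eta, tol=solver_tol)
        active = np.flatnonzero(eta)
        theta[:, eta == 0] = 0.0  # hierarchy: dead main kills its interactions

        # theta step: lasso on eta_k * E_j * X_k columns for active features
        if not no_theta and active.size:
            W = np.concatenate(
                [eta[k] * E * X[:, [k]] for k in active], axis=1
            )  # n x (J * |active|), column order (k outer, j inner)
            r = s * (y - X @ eta)
            th = _lasso(proj(s[:, None] * W), proj(r),
                        lambda2, warm=theta[:, active].T.ravel(), tol=solver_tol)
            theta[:, active] = th.reshape(active.size, J).T

        # tau step: exact least squares given the penalized blocks
        f_pen = X @ eta + ((E @ theta) * X) @ eta if not no_theta else X @ eta
        tau = proj.solve_tau(s * (y - f_pen))

        cur = objective(tau, eta, theta)
        obj_path.append(cur)
        # Two stopping rules. The objective can plateau for one sweep in
        # the product-term valley and then keep decreasing, so a small
        # positive decrement is not evidence of convergence (hence the
        # coefficient-change criterion); conversely, once the objective
        # stops strictly decreasing the iterates only drift along a flat
        # set and there is nothing left to gain.
        coefs = np.concatenate([tau, eta, theta.ravel()])
        if len(obj_path) >= 2 and obj_path[-2] - cur <= 0.0:
            converged = True
            break
        if prev_coefs is not None:
            delta = np.abs(coefs - prev_coefs).max()
            if delta <= tol * max(1.0, np.abs(coefs).max()):
                converged = True
                break
        prev_coefs = coefs
    if not converged and warn:
        warnings.warn(
            f"alternating solver did not converge in {max_iter} iterations", RuntimeWarning
        )
    theta[:, eta == 0] = 0.0
    return {
        "tau": tau,
        "eta": eta,
        "theta": theta,
        "objective": obj_path[-1],
        "objective_path": np.asarray(obj_path),
        "n_iter": n_iter,
        "converged": converged,
    }


def _lambda1_max(proj: _Projector, Xs: np.ndarray, ys: np.ndarray) -> float:
    """Smallest penalty zeroing all imaging mains (on row-scaled data)."""
    return float(2 * np.abs(proj(Xs).T @ proj(ys)).max())


def _weighted_rss(y, E, X, res, s):
    f = E @ res["tau"] + X @ res["eta"] + ((E @ res["theta"]) * X) @ res["eta"]
    r = y - f if s is None else s * (y - f)
    return float((r**2).sum())


def _grid(lam_max: float, n_points: int, min_ratio: float) -> np.ndarray:
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * min_ratio, n_points)


class HierarchicalInteractionLasso(BaseEstimator, RegressorMixin):
    """Hierarchy-respecting lasso for imaging-environment interactions.

    scikit-learn style estimator. ``fit(X, y, E=...)`` takes the N x K
    imaging matrix as ``X``, the outcome as ``y`` and the N x J clinical
    matrix through the ``E`` fit parameter; ``sample_weight`` carries
    Kaplan-Meier weights for censored outcomes (pass the data pre-sorted
    to match the weights). When ``lambda1``/``lambda2`` are None the
    penalties are tuned on a log-spaced grid by EBIC, warm-starting
    along decreasing lambda1, with ties broken toward the sparser
    (larger-penalty) corner.

    Attributes
    ----------
    tau_, eta_, theta_, gamma_ :
        Clinical mains (J,), imaging mains (K,), product factors (J, K)
        and interaction coefficients ``gamma_ = eta_ * theta_`` (J, K),
        on the internally standardized scale.
    lambda1_, lambda2_ : penalties actually used.
    ebic_, ebic_path_ : EBIC of the fitted model; tuning records.
    objective_path_ : objective value after each alternation sweep.
    """

    def __init__(
        self,
        lambda1: float | None = None,
        lambda2: float | None = None,
        n_lambda1: int = 20,
        n_lambda2: int = 20,
        lambda_min_ratio: float = 1e-3,
        max_active: int | None = None,
        ebic_gamma: float = 0.5,
        tol: float = 1e-9,
        max_iter: int = 200,
        standardize: bool = True,
        solver_tol: float = 1e-8,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.n_lambda1 = n_lambda1
        self.n_lambda2 = n_lambda2
        self.lambda_min_ratio = lambda_min_ratio
        self.max_active = max_active
        self.ebic_gamma = ebic_gamma
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.solver_tol = solver_tol

    # -- internal ------------------------------------------------------
    def _prepare(self, X, y, E, sample_weight):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if E is None:
            raise ValueError("the clinical matrix E is required (fit param E=...)")
        E = np.asarray(E, dtype=float)
        n = len(y)
        if X.shape[0] != n or E.shape[0] != n:
            raise ValueError("X, E and y must have matching numbers of rows")
        if n <= E.shape[1]:
            raise ValueError("need more subjects than clinical variables")
        w = None if sample_weight is None else np.asarray(sample_weight, float).ravel()
        yc, y_mean = center_columns(y, w)
        Ec, e_means = center_columns(E, w)
        if self.standardize:
            Xc, x_means, x_scales = standardize_columns(X, w)
        else:
            Xc, x_means = center_columns(X, w)
            x_scales = np.ones(X.shape[1])
        s = None if w is None else np.sqrt(w)
        self.y_mean_ = float(y_mean[0])
        self.e_means_, self.x_means_, self.x_scales_ = e_means, x_means, x_scales
        return yc, Ec, Xc, s

    def _p_total(self, J: int, K: int) -> int:
        return K + J * K

    def _df(self, res: dict, J: int) -> int:
        return int(np.count_nonzero(res["eta"]) + np.count_nonzero(res["theta"]) + J)

    def _theta_grid(self, proj, E, X, y, res, s):
        """Data-driven lambda2 grid at the current main-effects solution."""
        active = np.flatnonzero(res["eta"])
        if not active.size:
            return None
        W = np.concatenate([res["eta"][k] * E * X[:, [k]] for k in active], axis=1)
        r = y - X @ res["eta"]
        if s is not None:
            W, r = s[:, None] * W, s * r
        lam2_max = float(2 * np.abs(proj(W).T @ proj(r)).max())
        if lam2_max <= 0:
            return None
        return _grid(lam2_max, self.n_lambda2, self.lambda_min_ratio)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, E=None, sample_weight=None):
        yc, Ec, Xc, sc = self._prepare(X, y, E, sample_weight)
        n, K = Xc.shape
        J = Ec.shape[1]
        proj = _Projector(Ec if sc is None else sc[:, None] * Ec)
        solver = dict(tol=self.tol, max_iter=self.max_iter, proj=proj,
                      solver_tol=self.solver_tol, s=sc)

        if self.lambda1 is not None and self.lambda2 is not None:
            res = _alternate(yc, Ec, Xc, self.lambda1, self.lambda2, **solver)
            self.lambda1_, self.lambda2_ = float(self.lambda1), float(self.lambda2)
            self.ebic_path_ = None
        else:
            res, path = self._tune(yc, Ec, Xc, proj, solver, sc)
            self.ebic_path_ = pd.DataFrame(path)
        rss = _weighted_rss(yc, Ec, Xc, res, sc)
        self.ebic_ = ebic_score(rss, n, self._df(res, J), self._p_total(J, K), self.ebic_gamma)
        self.rss_ = rss
        self.tau_, self.eta_, self.theta_ = res["tau"], res["eta"], res["theta"]
        self.gamma_ = self.eta_[None, :] * self.theta_
        self.objective_ = res["objective"]
        self.objective_path_ = res["objective_path"]
        self.n_iter_ = res["n_iter"]
        self.n_features_in_ = K
        return self

    def _tune(self, yc, Ec, Xc, proj, solver, sc):
        n, K = Xc.shape
        J = Ec.shape[1]
        p_total = self._p_total(J, K)
        # model selection tolerates looser per-point solves; the winning
        # (lambda1, lambda2) pair is refit at full tolerance afterwards
        solver = solver | dict(tol=max(solver["tol"], 1e-4),
                               max_iter=min(solver["max_iter"], 8), warn=False,
                               solver_tol=max(solver["solver_tol"], 1e-7))
        Xs = Xc if sc is None else sc[:, None] * Xc
        ys = yc if sc is None else sc * yc
        lam1_grid = _grid(_lambda1_max(proj, Xs, ys), self.n_lambda1, self.lambda_min_ratio)
        fixed1 = self.lambda1 is not None
        fixed2 = self.lambda2 is not None
        if fixed1:
            lam1_grid = np.array([float(self.lambda1)])
        n_eff = n if sc is None else int(np.count_nonzero(sc))
        cap = self.max_active if self.max_active is not None else max(10, n_eff // 2)
        best = None
        best_key = np.inf
        path = []
        warm_eta = None
        for lam1 in lam1_grid:
            base = _alternate(yc, Ec, Xc, lam1, np.inf, eta0=warm_eta, **solver)
            warm_eta = base["eta"]
            if np.count_nonzero(base["eta"]) > cap:
                logger.debug("lambda1 path truncated at %.3g (active set > %d)", lam1, cap)
                break
            if fixed2:
                lam2_grid = np.array([float(self.lambda2)])
            else:
                grid = self._theta_grid(proj, Ec, Xc, yc, base, sc)
                lam2_grid = np.array([np.inf]) if grid is None else np.concatenate(
                    ([np.inf], grid)
                )
            warm = (base["eta"], base["theta"])
            for lam2 in lam2_grid:
                if np.isinf(lam2) and not fixed2:
                    res = base
                else:
                    res = _alternate(
                        yc, Ec, Xc, lam1, lam2, eta0=warm[0], theta0=warm[1], **solver
                    )
                    warm = (res["eta"], res["theta"])
                rss = _weighted_rss(yc, Ec, Xc, res, sc)
                score = ebic_score(rss, n, self._df(res, J), p_total, self.ebic_gamma)
                path.append(
                    {"lambda1": lam1, "lambda2": lam2, "df": self._df(res, J),
                     "rss": rss, "ebic": score}
                )
                if score < best_key:  # strict: ties keep the sparser, earlier corner
                    best_key = score
                    best = res
                    self.lambda1_, self.lambda2_ = float(lam1), float(lam2)
                if np.count_nonzero(res["theta"]) > cap:
                    break  # denser interaction sets cannot win EBIC either
        if best is None:
            raise RuntimeError("every tuning-grid fit failed")
        final = _alternate(
            yc, Ec, Xc, self.lambda1_, self.lambda2_,
            eta0=best["eta"], theta0=best["theta"],
            proj=proj, s=sc, tol=self.tol, max_iter=self.max_iter,
            solver_tol=self.solver_tol,
        )
        return final, path

    def predict(self, X, E=None):
        if E is None:
            raise ValueError("predict requires the clinical matrix E")
        X = np.asarray(X, dtype=float)
        E = np.asarray(E, dtype=float)
        Ec = E - self.e_means_
        Xc = (X - self.x_means_) / self.x_scales_
        f = Ec @ self.tau_ + Xc @ self.eta_ + ((Ec @ self.theta_) * Xc) @ self.eta_
        return f + self.y_mean_

    # -- selection reporting -------------------------------------------
    @property
    def selected_main_(self) -> np.ndarray:
        """Indices of imaging features with nonzero main effect."""
        return np.flatnonzero(self.eta_)

    @property
    def selected_interactions_(self) -> list[tuple[int, int]]:
        """(clinical j, feature k) pairs with nonzero interaction."""
        jj, kk = np.nonzero(self.gamma_)
        return list(zip(jj.tolist(), kk.tolist()))


class MainEffectsLasso(HierarchicalInteractionLasso):
    """Comparator: clinical variables plus imaging mains, no interactions.

    Equivalent to the hierarchical model with lambda2 = inf (theta frozen
    at zero); the single penalty on the imaging mains is EBIC-tuned when
    ``lambda1`` is None. Clinical effects remain unpenalized.
    """

    def __init__(
        self,
        lambda1: float | None = None,
        n_lambda1: int = 20,
        lambda_min_ratio: float = 1e-3,
        max_active: int | None = None,
        ebic_gamma: float = 0.5,
        tol: float = 1e-9,
        max_iter: int = 200,
        standardize: bool = True,
        solver_tol: float = 1e-8,
    ):
        super().__init__(
            lambda1=lambda1,
            lambda2=np.inf,
            n_lambda1=n_lambda1,
            n_lambda2=1,
            lambda_min_ratio=lambda_min_ratio,
            max_active=max_active,
            ebic_gamma=ebic_gamma,
            tol=tol,
            max_iter=max_iter,
            standardize=standardize,
            solver_tol=solver_tol,
        )

    def _p_total(self, J: int, K: int) -> int:
        return K

    def fit(self, X, y, E=None, sample_weight=None):
        yc, Ec, Xc, sc = self._prepare(X, y, E, sample_weight)
        n, K = Xc.shape
        J = Ec.shape[1]
        proj = _Projector(Ec if sc is None else sc[:, None] * Ec)
        solver = dict(tol=self.tol, max_iter=self.max_iter, proj=proj,
                      solver_tol=self.solver_tol, s=sc)
        Xs = Xc if sc is None else sc[:, None] * Xc
        ys = yc if sc is None else sc * yc
        if self.lambda1 is not None:
            res = _alternate(yc, Ec, Xc, float(self.lambda1), np.inf, **solver)
            self.lambda1_, self.lambda2_ = float(self.lambda1), np.inf
            self.ebic_path_ = None
        else:
            n_eff = n if sc is None else int(np.count_nonzero(sc))
            cap = self.max_active if self.max_active is not None else max(10, n_eff // 2)
            loose = solver | dict(tol=max(solver["tol"], 1e-4),
                                  max_iter=min(solver["max_iter"], 8), warn=False,
                                  solver_tol=max(solver["solver_tol"], 1e-7))
            best = None
            best_key = np.inf
            path = []
            warm = None
            for lam1 in _grid(_lambda1_max(proj, Xs, ys), self.n_lambda1, self.lambda_min_ratio):
                r = _alternate(yc, Ec, Xc, lam1, np.inf, eta0=warm, **loose)
                warm = r["eta"]
                if np.count_nonzero(r["eta"]) > cap:
                    break
                rss = _weighted_rss(yc, Ec, Xc, r, sc)
                score = ebic_score(rss, n, self._df(r, J), K, self.ebic_gamma)
                path.append({"lambda1": lam1, "lambda2": np.inf, "df": self._df(r, J),
                             "rss": rss, "ebic": score})
                if score < best_key:
                    best_key = score
                    best = r
                    self.lambda1_, self.lambda2_ = float(lam1), np.inf
            res = _alternate(yc, Ec, Xc, self.lambda1_, np.inf, eta0=best["eta"],
                             **solver)
            self.ebic_path_ = pd.DataFrame(path)
        rss = _weighted_rss(yc, Ec, Xc, res, sc)
        self.ebic_ = ebic_score(rss, n, self._df(res, J), self._p_total(J, K), self.ebic_gamma)
        self.rss_ = rss
        self.tau_, self.eta_, self.theta_ = res["tau"], res["eta"], res["theta"]
        self.gamma_ = self.eta_[None, :] * self.theta_
        self.objective_ = res["objective"]
        self.objective_path_ = res["objective_path"]
        self.n_iter_ = res["n_iter"]
        self.n_features_in_ = K
        return self


# ---------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------

def _config_kwargs(config: PenaltyConfig | None) -> dict:
    config = config or PenaltyConfig()
    return dict(
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        n_lambda1=config.n_lambda1,
        n_lambda2=config.n_lambda2,
        lambda_min_ratio=config.lambda_min_ratio,
        max_active=config.max_active,
        ebic_gamma=config.ebic_gamma,
        tol=config.tol,
        max_iter=config.max_iter,
        solver_tol=config.solver_tol,
    )


def fit_hier_lasso(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    config: PenaltyConfig | None = None,
    weights: np.ndarray | None = None,
    standardize: bool = False,
) -> HierarchicalInteractionLasso:
    """Fit the joint model at fixed penalties on prepared (centered) data.

    By default assumes y, E centered and X standardized already (pass
    ``standardize=True`` to let the estimator do it).
    """
    kw = _config_kwargs(config)
    if kw["lambda1"] is None or kw["lambda2"] is None:
        raise ValueError("fit_hier_lasso needs fixed lambda1 and lambda2; use tune() otherwise")
    model = HierarchicalInteractionLasso(standardize=standardize, **kw)
    return model.fit(X, y, E=E, sample_weight=weights)


def fit_main_only_lasso(
    y, E, X, lam: float | None = None, weights=None, config: PenaltyConfig | None = None,
    standardize: bool = False,
) -> MainEffectsLasso:
    """Main-effects-only lasso comparator (theta identically zero)."""
    kw = _config_kwargs(config)
    kw.pop("lambda2")
    kw.pop("n_lambda2")
    if lam is not None:
        kw["lambda1"] = lam
    model = MainEffectsLasso(standardize=standardize, **kw)
    return model.fit(X, y, E=E, sample_weight=weights)


def tune(
    y, E, X, config: PenaltyConfig | None = None, weights=None, standardize: bool = False
) -> tuple[HierarchicalInteractionLasso, pd.DataFrame]:
    """EBIC grid search over (lambda1, lambda2); returns (model, path)."""
    kw = _config_kwargs(config)
    model = HierarchicalInteractionLasso(standardize=standardize, **kw)
    model.fit(X, y, E=E, sample_weight=weights)
    return model, model.ebic_path_


def predict_joint(model: HierarchicalInteractionLasso, E, X) -> np.ndarray:
    """Evaluate f(E, X) for a fitted joint model (plus stored outcome mean)."""
    return model.predict(np.asarray(X, float), E=np.asarray(E, float))


def fit_joint(
    dataset: Dataset,
    config: PenaltyConfig | None = None,
    main_only: bool = False,
) -> HierarchicalInteractionLasso:
    """Fit the joint model to a dataset, routing censored outcomes via AFT/KM.

    Continuous outcomes are modelled directly; survival outcomes are
    log-transformed, sorted, and fitted by KM-weighted least squares.
    """
    if isinstance(dataset.outcome, SurvivalOutcome):
        yv, delta, order = to_aft_scale(
            dataset.outcome.time, dataset.outcome.status, dataset.subject_ids
        )
        w = km_weights(delta).w
        Ev, Xv = dataset.E.values[order], dataset.X.values[order]
    else:
        yv, w = dataset.outcome.y, None
        Ev, Xv = dataset.E.values, dataset.X.values
    kw = _config_kwargs(config)
    if main_only:
        kw.pop("lambda2")
        kw.pop("n_lambda2")
        model = MainEffectsLasso(standardize=True, **kw)
    else:
        model = HierarchicalInteractionLasso(standardize=True, **kw)
    model.fit(Xv, yv, E=Ev, sample_weight=w)
    model.feature_names_ = list(dataset.X.feature_names)
    model.feature_groups_ = list(dataset.X.feature_groups)
    model.clinical_names_ = list(dataset.E.variable_names)
    return model
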