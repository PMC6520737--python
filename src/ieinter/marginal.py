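"""Marginal imaging-environment interaction scan.

One clinical/environmental variable E_j, one imaging feature X_k and
their product are analysed at a time with the centered, no-intercept
linear model

    Y = alpha_j E_j + beta_k X_k + gamma_jk E_j X_k + eps,

for all J x K pairs. Interactions (optionally together with imaging
main effects) with small multiplicity-adjusted p-values are flagged.
For censored outcomes the same models are fitted by Kaplan-Meier
weighted least squares on the AFT (log-time) scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .data import Dataset, SurvivalOutcome, center_columns, standardize_columns
from .survival import km_weights, to_aft_scale

logger = logging.getLogger(__name__)

__all__ = [
    "TripleFit",
    "MarginalInteractionScan",
    "fit_single_interaction",
    "scan",
    "adjust_pvalues",
    "power_analysis",
]


@dataclass
class TripleFit:
    """Estimates for one (clinical variable, imaging feature) pair."""

    alpha: float
    beta: float
    gamma: float
    se: np.ndarray  # (se_alpha, se_beta, se_gamma)
    pvalues: np.ndarray  # matching two-sided p-values
    resid_var: float
    df_resid: int


def fit_single_interaction(
    y: np.ndarray,
    e: np.ndarray,
    x: np.ndarray,
    weights: np.ndarray | None = None,
) -> TripleFit:
    """(Weighted) least squares for the three-coefficient pair model.

    Inputs are assumed centered (weighted-centered when ``weights`` are
    KM weights), so no intercept is fitted. Standard errors come from
    the (weighted) information matrix with the error variance estimated
    on N - 3 degrees of freedom, and two-sided p-values from the
    t(N - 3) reference.
    """
    y = np.asarray(y, float).ravel()
    e = np.asarray(e, float).ravel()
    x = np.asarray(x, float).ravel()
    n = len(y)
    if not (len(e) == len(x) == n):
        raise ValueError("y, e, x must have equal length")
    if n < 5:
        raise ValueError("need at least 5 subjects for the pair model")
    D = np.column_stack([e, x, e * x])
    w = np.ones(n) if weights is None else np.asarray(weights, float).ravel()
    Dw = D * w[:, None]
    XtX = D.T @ Dw
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("collinear design in pair model (e.g. x proportional to e)")
    coef = np.linalg.solve(XtX, D.T @ (w * y))
    resid = y - D @ coef
    df = n - 3
    rss = float(w @ resid**2)
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    if sigma2 <= np.finfo(float).eps * max(1.0, float(w @ y**2)):
        logger.warning("degenerate fit: zero residual variance; p-values set to 0")
        pvals = np.zeros(3)
    else:
        tstat = coef / se
        pvals = 2 * stats.t.sf(np.abs(tstat), df)
    return TripleFit(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        gamma=float(coef[2]),
        se=se,
        pvalues=pvals,
        resid_var=sigma2,
        df_resid=df,
    )


def adjust_pvalues(p: np.ndarray, method: str = "fdr") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg FDR or Bonferroni.

    Order-preserving with the input; BH values are the step-up adjusted
    p-values with monotonicity enforced, Bonferroni is min(1, m*p).
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size and (np.any(p < 0) | np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    if method == "fdr":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    raise ValueError(f"unknown adjustment method {method!r}")


class MarginalInteractionScan(BaseEstimator):
    """Scan all J x K single-pair interaction models.

    Parameters
    ----------
    adjust : {"fdr", "bonferroni"}
        Multiplicity adjustment applied within the discovery family.
    family : {"interaction", "interaction+main"}
        Which coefficient roles form the discovery family. The default
        adjusts interaction p-values only; the alternative pools the
        imaging main-effect and interaction p-values into one family.
    standardize : bool
        Standardize imaging features (and center everything) before
        fitting, so estimates are on a comparable per-SD scale.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (pair, role) with columns feature_group,
        feature_name, partner, clinical_variable, estimate, se, p_raw,
        p_adjusted; sorted by interaction p_raw ascending within role.
    failures_ : list of (j, k, reason) for pairs that could not be fit.
    """

    def __init__(
        self,
        adjust: str = "fdr",
        family: str = "interaction",
        standardize: bool = True,
    ):
        self.adjust = adjust
        self.family = family
        self.standardize = standardize

    def fit(self, dataset: Dataset):
        E, X = dataset.E, dataset.X
        if isinstance(dataset.outcome, SurvivalOutcome):
            y, delta, order = to_aft_scale(
                dataset.outcome.time, dataset.outcome.status, dataset.subject_ids
            )
            w = km_weights(delta).w
            Evals, Xvals = E.values[order], X.values[order]
        else:
            y = dataset.outcome.y
            w = None
            Evals, Xvals = E.values, X.values

        yc, _ = center_columns(y, w)
        Ec, _ = center_columns(Evals, w)
        if self.standardize:
            Xc, _, _ = standardize_columns(Xvals, w)
        else:
            Xc, _ = center_columns(Xvals, w)

        rows = []
        self.failures_: list[tuple[int, int, str]] = []
        for j, ename in enumerate(E.variable_names):
            for k, fname in enumerate(X.feature_names):
                try:
                    fit = fit_single_interaction(yc, Ec[:, j], Xc[:, k], w)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    self.failures_.append((j, k, str(exc)))
                    continue
                base = {
                    "feature_group": X.feature_groups[k],
                    "feature_name": fname,
                    "clinical_variable": ename,
                }
                rows.append(
                    base | {"partner": "Main", "estimate": fit.beta,
                            "se": fit.se[1], "p_raw": fit.pvalues[1]}
                )
                rows.append(
                    base | {"partner": ename, "estimate": fit.gamma,
                            "se": fit.se[2], "p_raw": fit.pvalues[2]}
                )
        table = pd.DataFrame(rows)
        if table.empty:
            raise ValueError("every pair model failed; nothing to report")
        is_int = table["partner"] != "Main"
        table["p_adjusted"] = np.nan
        if self.family == "interaction":
            fam = is_int
        elif self.family == "interaction+main":
            fam = pd.Series(True, index=table.index)
        else:
            raise ValueError(f"unknown discovery family {self.family!r}")
        table.loc[fam, "p_adjusted"] = adjust_pvalues(
            table.loc[fam, "p_raw"].to_numpy(), self.adjust
        )
        # interaction rows first by raw p-value, then main rows
        table = table.sort_values(
            ["partner", "p_raw"],
            key=lambda c: c.map(lambda v: (v == "Main")) if c.name == "partner" else c,
            kind="stable",
        ).reset_index(drop=True)
        self.results_ = table
        return self

    def top(self, n: int = 10, role: str = "interaction") -> pd.DataFrame:
        """Top-n rows of one role by raw p-value (presentation helper)."""
        t = self.results_
        mask = (t["partner"] != "Main") if role == "interaction" else (t["partner"] == "Main")
        return t[mask].nsmallest(n, "p_raw")


def scan(dataset: Dataset, adjust: str = "fdr", family: str = "interaction") -> pd.DataFrame:
    """Functional wrapper around :class:`MarginalInteractionScan`."""
    return MarginalInteractionScan(adjust=adjust, family=family).fit(dataset).results_


def power_analysis(
    effect: float | None = None,
    sd: float = 1.0,
    mode: str = "required_n",
    n: int | None = None,
    alpha: float = 0.05,
    power: float = 0.8,
) -> float:
    """Two-sided normal-approximation power calculation for one pair test.

    ``required_n`` solves ceil(((z_{1-alpha/2} + z_power) * sd / |effect|)^2);
    ``detectable_effect`` inverts the same formula at a given n. A
    multiple-testing target (e.g. FDR 0.1 at a given rank) is mapped to a
    per-test ``alpha`` by the caller — for BH at rank r of m tests the
    per-test level is q * r / m.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    if mode == "required_n":
        if effect is None or effect == 0:
            raise ValueError("cannot solve for n with a null effect")
        return float(math.ceil((z * sd / abs(effect)) ** 2 - 1e-9))
    if mode == "detectable_effect":
        if n is None or n <= 0:
            raise ValueError("detectable_effect mode needs a positive n")
        return float(z * sd / math.sqrt(n))
    raise ValueError(f"unknown mode {mode!r}")
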