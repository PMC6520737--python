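"""Model assessment: resampled prediction error, risk groups, selection overlap.

Prediction is evaluated by repeated random train/test splits: models
(including their internal penalty tuning) are refitted on each training
set and scored on the held-out subjects — prediction mean squared error
(PMSE) for continuous outcomes, and for censored outcomes a median split
of predicted log survival times into low/high risk groups compared by
the two-sample logrank test. Agreement between the effect sets chosen by
two procedures is quantified by overlap counts and by the RV coefficient
of the corresponding design submatrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .data import ContinuousOutcome, Dataset, SurvivalOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "pmse_resampling",
    "risk_stratify_logrank",
    "rv_coefficient",
    "selection_overlap",
]


@dataclass
class EvaluationReport:
    """Per-fitter resampling summary."""

    pmse_mean: dict[str, float] = field(default_factory=dict)
    pmse_sd: dict[str, float] = field(default_factory=dict)
    logrank_mean: dict[str, float] = field(default_factory=dict)
    logrank_p_of_mean: dict[str, float] = field(default_factory=dict)
    logrank_mean_p: dict[str, float] = field(default_factory=dict)
    n_effective: dict[str, int] = field(default_factory=dict)
    n_rep: int = 0
    train_fraction: float = 0.75
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        names = sorted(
            set(self.pmse_mean) | set(self.logrank_mean) | set(self.n_effective)
        )
        rows = []
        for name in names:
            rows.append(
                {
                    "fitter": name,
                    "pmse_mean": self.pmse_mean.get(name),
                    "pmse_sd": self.pmse_sd.get(name),
                    "logrank_mean": self.logrank_mean.get(name),
                    "logrank_p_of_mean": self.logrank_p_of_mean.get(name),
                    "logrank_mean_p": self.logrank_mean_p.get(name),
                    "n_effective": self.n_effective.get(name),
                }
            )
        return pd.DataFrame(rows)


def _subset(dataset: Dataset, idx: np.ndarray) -> Dataset:
    from .data import ClinicalMatrix, FeatureMatrix

    if isinstance(dataset.outcome, SurvivalOutcome):
        outcome = SurvivalOutcome(dataset.outcome.time[idx], dataset.outcome.status[idx])
    else:
        outcome = ContinuousOutcome(dataset.outcome.y[idx])
    return Dataset(
        E=ClinicalMatrix(dataset.E.values[idx], list(dataset.E.variable_names)),
        X=FeatureMatrix(
            dataset.X.values[idx],
            list(dataset.X.feature_names),
            list(dataset.X.feature_groups),
        ),
        outcome=outcome,
        subject_ids=[dataset.subject_ids[i] for i in idx],
    )


def pmse_resampling(
    dataset: Dataset,
    fitters: dict[str, Callable[[Dataset], object]],
    n_rep: int = 100,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated random-split prediction evaluation.

    ``fitters`` maps a name to a callable taking a training Dataset and
    returning a fitted object with ``predict(X, E=...)``. Each
    repetition draws a fresh split; fitting (with any internal tuning)
    happens on the training part only. For continuous outcomes PMSE is
    recorded; for survival outcomes the test subjects are risk-stratified
    at the median predicted log time and the logrank statistic recorded.
    A fitter failure on one split skips that split for that fitter.
    """
    if n_rep < 1 or not 0 < train_fraction < 1:
        raise ValueError("need n_rep >= 1 and train_fraction in (0, 1)")
    n = dataset.n_subjects
    rng = np.random.default_rng(seed)
    survival = isinstance(dataset.outcome, SurvivalOutcome)
    pmse: dict[str, list[float]] = {name: [] for name in fitters}
    lr_stat: dict[str, list[float]] = {name: [] for name in fitters}
    lr_p: dict[str, list[float]] = {name: [] for name in fitters}

    n_train = max(1, int(round(train_fraction * n)))
    for rep in range(n_rep):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if survival and dataset.outcome.status[train].sum() == 0:
            logger.warning("split %d has no training events; skipped", rep)
            continue
        ds_train = _subset(dataset, train)
        Xte, Ete = dataset.X.values[test], dataset.E.values[test]
        for name, fitter in fitters.items():
            try:
                model = fitter(ds_train)
                pred = model.predict(Xte, E=Ete)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fitter %s failed on split %d: %s", name, rep, exc)
                continue
            if survival:
                try:
                    stat, p, _ = risk_stratify_logrank(
                        pred, dataset.outcome.time[test], dataset.outcome.status[test]
                    )
                except ValueError as exc:
                    logger.warning("logrank skipped for %s on split %d: %s", name, rep, exc)
                    continue
                lr_stat[name].append(stat)
                lr_p[name].append(p)
            else:
                err = dataset.outcome.y[test] - pred
                pmse[name].append(float(np.mean(err**2)))

    report = EvaluationReport(n_rep=n_rep, train_fraction=train_fraction, seed=seed)
    for name in fitters:
        if survival:
            vals = np.asarray(lr_stat[name])
            report.n_effective[name] = vals.size
            if vals.size:
                report.logrank_mean[name] = float(vals.mean())
                report.logrank_p_of_mean[name] = float(stats.chi2.sf(vals.mean(), 1))
                report.logrank_mean_p[name] = float(np.mean(lr_p[name]))
        else:
            vals = np.asarray(pmse[name])
            report.n_effective[name] = vals.size
            if vals.size:
                report.pmse_mean[name] = float(vals.mean())
                report.pmse_sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return report


def risk_stratify_logrank(
    predicted_log_times: np.ndarray,
    times: np.ndarray,
    status: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Median split of predicted survival into risk groups + logrank test.

    Subjects with predictions above the median form the low-risk group;
    ties at the median go to the high-risk group. Returns the logrank
    chi-square statistic, its 1-df upper-tail p-value and the group
    labels ("high"/"low").
    """
    pred = np.asarray(predicted_log_times, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    status = np.asarray(status).ravel().astype(int)
    if len(pred) < 4 or status.sum() < 1:
        raise ValueError("need at least 4 subjects and one event")
    med = np.median(pred)
    low = pred > med  # ties (== median) stay high-risk
    if low.all() or not low.any():
        raise ValueError("degenerate split: all predictions on one side of the median")
    res = logrank_test(times[low], times[~low], status[low], status[~low])
    labels = np.where(low, "low", "high")
    return float(res.test_statistic), float(res.p_value), labels


def rv_coefficient(A: np.ndarray, B: np.ndarray) -> float:
    """RV coefficient between two column-centered data matrices.

    trace(A A' B B') / sqrt(trace((A A')^2) * trace((B B')^2)),
    a [0, 1] matrix analogue of squared correlation; 1 means the two
    column spaces carry the same subject-by-subject configuration.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0] or A.shape[0] < 2:
        raise ValueError("A and B need matching row counts (N >= 2)")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    ctAB = np.sum((A.T @ B) ** 2)
    ctA = np.sum((A.T @ A) ** 2)
    ctB = np.sum((B.T @ B) ** 2)
    if ctA <= 0 or ctB <= 0:
        raise ValueError("RV coefficient undefined for an all-zero matrix")
    return float(ctAB / np.sqrt(ctA * ctB))


def selection_overlap(
    selected_a: Sequence, selected_b: Sequence
) -> tuple[int, int, int]:
    """Sizes of two selected-effect sets and of their intersection."""
    a, b = set(selected_a), set(selected_b)
    return len(a), len(b), len(a & b)
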