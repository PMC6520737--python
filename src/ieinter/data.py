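"""Domain containers, delimited-text I/O and table-level preprocessing.

The analysis consumes three patient-aligned tables: an N x K matrix of
quantitative histopathological imaging features (grouped into Texture,
Geometry and Holistic families), an N x J matrix of numerically coded
clinical/environmental covariates, and an outcome that is either a
continuous biomarker or a right-censored survival pair (time, status).

Preprocessing implemented here is exactly what the downstream models
assume: features with excessive missingness are dropped, remaining
missing cells are median-imputed, and all design columns are (optionally
weighted) mean-centered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_GROUPS = ("Texture", "Geometry", "Holistic")

__all__ = [
    "FeatureMatrix",
    "ClinicalMatrix",
    "ContinuousOutcome",
    "SurvivalOutcome",
    "Dataset",
    "read_dataset",
    "read_table",
    "impute_and_filter",
    "center_columns",
    "standardize_columns",
]


class FormatError(ValueError):
    """A table does not have the expected columns."""


class EmptyJoinError(ValueError):
    """No subject identifier is shared by all input tables."""


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if list(names).count(n) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class FeatureMatrix:
    """N x K real matrix of imaging features with group labels.

    ``feature_groups`` carries one label per feature, conventionally one
    of Texture / Geometry / Holistic for CellProfiler-style features,
    though arbitrary labels are accepted.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        n, k = self.values.shape
        if n < 2 or k < 1:
            raise ValueError(f"need N >= 2 and K >= 1, got shape {(n, k)}")
        if len(self.feature_names) != k:
            raise ValueError("feature_names length does not match K")
        _check_unique(self.feature_names, "feature names")
        if not self.feature_groups:
            self.feature_groups = ["Texture"] * k
        if len(self.feature_groups) != k:
            raise ValueError("feature_groups length does not match K")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names, index=index)


@dataclass
class ClinicalMatrix:
    """N x J numerically coded clinical/environmental covariates."""

    values: np.ndarray
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("clinical matrix must be 2-dimensional")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one clinical variable")
        if len(self.variable_names) != self.values.shape[1]:
            raise ValueError("variable_names length does not match J")
        _check_unique(self.variable_names, "clinical variable names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clinical matrix contains non-finite entries")

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass
class ContinuousOutcome:
    """Continuous outcome vector (e.g. an FEV1-like lung-function biomarker)."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("outcome contains non-finite values")


@dataclass
class SurvivalOutcome:
    """Right-censored follow-up: observed time min(T, C) and event indicator."""

    time: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.status = np.asarray(self.status).ravel()
        if len(self.time) != len(self.status):
            raise ValueError("time and status lengths differ")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = int(np.argmax(~(np.isfinite(self.time) & (self.time > 0))))
            raise ValueError(f"follow-up times must be positive and finite (row {bad})")
        bad = ~np.isin(self.status, (0, 1))
        if bad.any():
            raise ValueError(
                f"status must be 0 (censored) or 1 (event); offending rows: "
                f"{np.flatnonzero(bad)[:5].tolist()}"
            )
        self.status = self.status.astype(int)


Outcome = ContinuousOutcome | SurvivalOutcome


@dataclass
class Dataset:
    """Aligned (E, X, outcome) triplet for N subjects."""

    E: ClinicalMatrix
    X: FeatureMatrix
    outcome: Outcome
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.X.n_subjects
        if self.E.values.shape[0] != n:
            raise ValueError("clinical and feature matrices have different N")
        ylen = (
            len(self.outcome.y)
            if isinstance(self.outcome, ContinuousOutcome)
            else len(self.outcome.time)
        )
        if ylen != n:
            raise ValueError("outcome length does not match N")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match N")

    @property
    def n_subjects(self) -> int:
        return self.X.n_subjects

    @property
    def is_survival(self) -> bool:
        return isinstance(self.outcome, SurvivalOutcome)


def read_table(path, id_column: str = "id") -> pd.DataFrame:
    """Read a comma- or tab-delimited table indexed by subject ID."""
    df = pd.read_csv(path, sep=None, engine="python")
    if id_column not in df.columns:
        raise FormatError(f"{path}: missing required ID column {id_column!r}")
    df[id_column] = df[id_column].astype(str)
    if df[id_column].duplicated().any():
        raise FormatError(f"{path}: duplicated subject IDs")
    return df.set_index(id_column)


def read_dataset(
    features_path,
    clinical_path,
    outcome_path,
    outcome_kind: str = "continuous",
    id_column: str = "id",
    feature_groups: dict[str, str] | None = None,
) -> Dataset:
    """Load and align the three analysis tables on subject ID.

    Subjects present in all three tables are kept, in sorted-ID order
    (deterministic regardless of file row order); dropped subjects are
    counted in a log message.

    Parameters
    ----------
    outcome_kind:
        ``"continuous"`` expects a single value column; ``"survival"``
        expects ``time`` and ``status`` columns (status 1 = event).
    feature_groups:
        Optional feature-name -> group-label map. Features not in the
        map (or when the map is omitted) are labelled ``Texture``.
    """
    if outcome_kind not in ("continuous", "survival"):
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    feats = read_table(features_path, id_column)
    clin = read_table(clinical_path, id_column)
    outc = read_table(outcome_path, id_column)

    common = sorted(set(feats.index) & set(clin.index) & set(outc.index))
    if not common:
        raise EmptyJoinError("no subject IDs shared by all three tables")
    dropped = len(set(feats.index) | set(clin.index) | set(outc.index)) - len(common)
    if dropped:
        logger.info("dropped %d subjects missing from at least one table", dropped)

    feats, clin, outc = feats.loc[common], clin.loc[common], outc.loc[common]
    groups = [
        (feature_groups or {}).get(name, "Texture") for name in feats.columns
    ]
    X = FeatureMatrix(feats.to_numpy(float), list(feats.columns), groups)
    E = ClinicalMatrix(clin.to_numpy(float), list(clin.columns))

    outcome: Outcome
    if outcome_kind == "survival":
        if not {"time", "status"} <= set(outc.columns):
            raise FormatError("survival outcome table needs 'time' and 'status' columns")
        outcome = SurvivalOutcome(outc["time"].to_numpy(), outc["status"].to_numpy())
    else:
        value_cols = [c for c in outc.columns]
        if len(value_cols) != 1:
            raise FormatError(
                f"continuous outcome table must have exactly one value column, got {value_cols}"
            )
        outcome = ContinuousOutcome(outc[value_cols[0]].to_numpy())
    return Dataset(E=E, X=X, outcome=outcome, subject_ids=list(common))


def impute_and_filter(X: FeatureMatrix, max_missing_rate: float = 0.2) -> FeatureMatrix:
    """Drop high-missingness features, median-impute the rest.

    A feature whose fraction of missing entries is at or above
    ``max_missing_rate`` is removed; remaining missing cells are filled
    with the feature's median over observed values. Returns a new
    matrix with no missing entries.
    """
    if not 0 < max_missing_rate <= 1:
        raise ValueError("max_missing_rate must be in (0, 1]")
    vals = X.values.copy()
    miss = np.isnan(vals)
    rate = miss.mean(axis=0)
    keep = rate < max_missing_rate
    if not keep.any():
        raise ValueError("all features removed by the missingness filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d features with missing rate >= %.2f", dropped, max_missing_rate)
    vals = vals[:, keep]
    med = np.nanmedian(vals, axis=0)
    idx = np.where(np.isnan(vals))
    vals[idx] = med[idx[1]]
    out = FeatureMatrix(
        vals,
        [n for n, k in zip(X.feature_names, keep) if k],
        [g for g, k in zip(X.feature_groups, keep) if k],
    )
    out.validate_finite()
    return out


def center_columns(
    M: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the (weighted) column mean from each column.

    Returns the centered matrix and the vector of column means so that
    predictions can be mapped back to the original scale. Zero-variance
    columns are permitted (they become identically zero) but logged.
    """
    M = np.asarray(M, dtype=float)
    one_d = M.ndim == 1
    if one_d:
        M = M[:, None]
    if weights is None:
        means = M.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != M.shape[0]:
            raise ValueError("weights length does not match number of rows")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        means = (w[:, None] * M).sum(axis=0) / w.sum()
    centered = M - means
    degenerate = np.flatnonzero(np.ptp(M, axis=0) == 0)
    if degenerate.size:
        logger.info("columns %s have zero variance", degenerate[:5].tolist())
    if one_d:
        return centered.ravel(), means
    return centered, means


def standardize_columns(
    M: np.ndarray, weights: np.ndarray | None = None, min_scale: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale them to unit (weighted) standard deviation.

    Zero-variance columns get scale 1 so they pass through as zeros.
    Returns (standardized matrix, means, scales).
    """
    centered, means = center_columns(M, weights)
    if weights is None:
        scale = centered.std(axis=0)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        scale = np.sqrt((w[:, None] * centered**2).sum(axis=0) / w.sum())
    scale = np.where(scale < min_scale, 1.0, scale)
    return centered / scale, means, scale
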