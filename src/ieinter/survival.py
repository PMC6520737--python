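"""Accelerated-failure-time scale transformation and Kaplan-Meier weights.

Right-censored survival outcomes are handled by modelling log follow-up
time linearly (an AFT model) and reweighting squared-error loss with the
Kaplan-Meier (Stute) weights, the jump sizes of the KM estimator of the
time distribution. Censored subjects receive weight zero; the weighted
least-squares criterion sum_i w_i (y_i - f_i)^2 is then consistent under
independent right censoring. Every continuous-outcome routine in this
package becomes censoring-aware by running on the transformed data
returned by :func:`weighted_objective_transform`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import center_columns

__all__ = ["KMWeights", "to_aft_scale", "km_weights", "weighted_objective_transform"]


@dataclass
class KMWeights:
    """Stute weights aligned to subjects sorted by log observed time.

    ``w[i]`` is the KM jump at the i-th smallest observed time; zero for
    censored subjects. ``order`` maps sorted position -> original row.
    """

    w: np.ndarray
    order: np.ndarray
    n_ties: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        if np.any(self.w < 0):
            raise ValueError("KM weights must be nonnegative")

    @property
    def total_mass(self) -> float:
        return float(self.w.sum())


def to_aft_scale(
    times: np.ndarray,
    status: np.ndarray,
    subject_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort subjects by log observed time, events before censorings at ties.

    Returns ``(y, delta, order)`` where ``y = log(time)`` in ascending
    order, ``delta`` the matching event indicators and ``order`` the
    permutation applied (sorted position -> original row). Tied times are
    broken with events first — the standard convention for Stute weights,
    so that a censored subject at a tied time is still "at risk" when the
    event occurs — and then by subject ID for full determinism.
    """
    times = np.asarray(times, dtype=float).ravel()
    status = np.asarray(status).ravel().astype(int)
    if np.any(times <= 0):
        raise ValueError("follow-up times must be positive")
    if subject_ids is None:
        subject_ids = [f"{i:09d}" for i in range(len(times))]
    # lexsort: primary = time, secondary = censored-after-event, tertiary = ID
    order = np.lexsort((np.asarray(subject_ids), 1 - status, times))
    return np.log(times[order]), status[order], order


def km_weights(status_sorted: np.ndarray) -> KMWeights:
    """Kaplan-Meier (Stute) weights from sorted event indicators.

    With subjects sorted by observed time, the weights are

        w_1 = delta_1 / N,
        w_i = delta_i / (N - i + 1) * prod_{j<i} ((N - j)/(N - j + 1))^delta_j.

    They coincide with the KM jump sizes: uniform 1/N when every subject
    is an event, zero for censored subjects, and summing to one minus the
    survivor mass the KM curve leaves beyond the last observed event.
    """
    delta = np.asarray(status_sorted).ravel().astype(int)
    if not np.all(np.isin(delta, (0, 1))):
        raise ValueError("status values must be 0 or 1")
    n = len(delta)
    if n < 1:
        raise ValueError("need at least one subject")
    i = np.arange(1, n + 1)
    # cumulative product of ((N-j)/(N-j+1))^delta_j for j < i
    ratio = ((n - i) / (n - i + 1.0)) ** delta
    cumprod = np.concatenate(([1.0], np.cumprod(ratio)[:-1]))
    w = delta / (n - i + 1.0) * cumprod
    return KMWeights(w=w, order=np.arange(n))


def weighted_objective_transform(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    w: np.ndarray | KMWeights,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Fold KM weights into the data so unweighted machinery applies.

    Rows are weight-centered and then scaled by sqrt(w_i), so that an
    ordinary squared-error fit on the transformed data minimises
    sum_i w_i (y_i - f_i)^2 with weight-mean-zero columns. Zero-weight
    (censored) subjects end up as all-zero rows and have no influence on
    fitted coefficients.

    Returns (y_t, E_t, X_t, meta) where meta records the weighted means
    needed to move predictions back to the original scale.
    """
    wv = w.w if isinstance(w, KMWeights) else np.asarray(w, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if wv.sum() <= 0:
        raise ValueError("all KM weights are zero; no events to fit on")
    yc, y_mean = center_columns(y, wv)
    Ec, e_means = center_columns(E, wv)
    Xc, x_means = center_columns(X, wv)
    s = np.sqrt(wv)
    meta = {"y_mean": float(y_mean[0]), "e_means": e_means, "x_means": x_means}
    return s * yc, s[:, None] * Ec, s[:, None] * Xc, meta
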