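"""Label-specific feature selection by Pearson correlation.

For each location label, every GO feature column is scored by its
Pearson correlation r with the ±1 label-score column; features are
ranked by |r| (a strong negative correlation is as discriminative as a
strong positive one) and a per-label prefix of length K is retained.
The ranked prefixes are the "label-specific features" each binary
classifier is trained on. K can be fixed, a fraction of the feature
count ω, or chosen per label by an inner cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


def pearson(f: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation between a feature column and a label column.

    r = Σ(f_k − f̄)(y_k − ȳ) / √(Σ(f_k − f̄)² · Σ(y_k − ȳ)²).

    Returns 0.0 when either vector has zero variance: the formula is
    undefined there and a constant column cannot discriminate.
    """
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError(f"length mismatch: {f.shape} vs {y.shape}")
    if f.size < 2:
        raise ValueError("need at least two observations")
    fd = f - f.mean()
    yd = y - y.mean()
    denom = np.sqrt((fd @ fd) * (yd @ yd))
    if denom == 0.0:
        return 0.0
    return float((fd @ yd) / denom)


def column_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of ``X`` against ``y`` (vectorized).

    Zero-variance columns (or a zero-variance ``y``) get r = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = X - X.mean(axis=0)
    yd = y - y.mean()
    ss_x = (Xd * Xd).sum(axis=0)
    ss_y = yd @ yd
    denom = np.sqrt(ss_x * ss_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xd.T @ yd) / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def rank_features(
    X: np.ndarray, y: np.ndarray, *, key: str = "absolute"
) -> tuple[np.ndarray, np.ndarray]:
    """Rank feature columns by discriminativeness for one label.

    Returns ``(order, r)`` where ``order`` lists feature indices in
    descending |r| (``key="absolute"``, the default) or descending
    signed r (``key="signed"``); ties break by ascending feature index
    so the ordering is deterministic.
    """
    r = column_correlations(X, y)
    if key == "absolute":
        primary = -np.abs(r)
    elif key == "signed":
        primary = -r
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    order = np.lexsort((np.arange(r.size), primary))
    return order, r


# ---------------------------------------------------------------------------
# K policies


@dataclass(frozen=True)
class FixedK:
    """Keep the same fixed number of top-ranked features for every label."""

    k: int


@dataclass(frozen=True)
class FractionK:
    """Keep a fixed fraction of ω for every label (``FractionK(1.0)`` keeps all)."""

    fraction: float

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


@dataclass(frozen=True)
class InnerCVK:
    """Choose K per label by inner stratified cross-validation.

    Candidate K values are fractions of ω; the winner maximizes mean
    binary F1 of the base learner over the folds (ties favour the
    smaller K). Folds are unshuffled, so the choice is deterministic.
    When a label has too few members of either class to stratify,
    the fallback fraction is used instead.
    """

    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    n_splits: int = 3
    fallback_fraction: float = 0.3


KPolicy = FixedK | FractionK | InnerCVK


@dataclass
class LabelSpecificSelection:
    """Per-label ranked feature indices, their r values, and the chosen K."""

    orders: list[np.ndarray]
    correlations: list[np.ndarray]
    k_values: list[int]
    labels: tuple[str, ...]

    @property
    def c(self) -> int:
        return len(self.labels)

    def indices_for(self, label_index: int) -> np.ndarray:
        """The selected (ranked prefix) feature indices for one label."""
        return self.orders[label_index][: self.k_values[label_index]]

    def to_frame(self, terms: Sequence[str] | None = None) -> pd.DataFrame:
        """Selection report: one row per (label, rank)."""
        rows = []
        for i, label in enumerate(self.labels):
            k = self.k_values[i]
            for rank, feature in enumerate(self.orders[i]):
                rows.append(
                    {
                        "label": label,
                        "rank": rank,
                        "feature_index": int(feature),
                        "term": terms[feature] if terms is not None else str(feature),
                        "r": self.correlations[i][feature],
                        "selected": rank < k,
                    }
                )
        return pd.DataFrame(rows)


def _clamp_k(k: int, omega: int) -> int:
    if k > omega:
        logger.warning("K=%d exceeds omega=%d; clamped", k, omega)
        return omega
    return max(1, k)


def _cv_choose_k(
    X: np.ndarray,
    y: np.ndarray,
    policy: InnerCVK,
    base_learner,
    ranking: str,
) -> int:
    """Inner-CV grid search over candidate K for one label.

    Ranking is recomputed inside each training fold so the choice of K
    is free of selection leakage from the validation part.
    """
    omega = X.shape[1]
    candidates = sorted(
        {_clamp_k(max(1, round(f * omega)), omega) for f in policy.fractions}
    )
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if min(n_pos, n_neg) < policy.n_splits:
        return _clamp_k(max(1, round(policy.fallback_fraction * omega)), omega)
    splitter = StratifiedKFold(n_splits=policy.n_splits, shuffle=False)
    scores = np.zeros(len(candidates))
    for train_rows, val_rows in splitter.split(X, y):
        order, _ = rank_features(X[train_rows], y[train_rows], key=ranking)
        for j, k in enumerate(candidates):
            cols = order[:k]
            est = clone(base_learner)
            est.fit(X[np.ix_(train_rows, cols)], y[train_rows])
            predicted = est.predict(X[np.ix_(val_rows, cols)])
            scores[j] += f1_score(y[val_rows], predicted, pos_label=1, zero_division=0)
    return candidates[int(np.argmax(scores))]  # argmax ties -> smallest K


def select(
    dataset,
    policy: KPolicy = InnerCVK(),
    *,
    base_learner=None,
    ranking: str = "absolute",
) -> LabelSpecificSelection:
    """Build the label-specific selection for every label of a dataset."""
    from .model import default_base_learner  # avoid import cycle

    if base_learner is None:
        base_learner = default_base_learner()
    omega = dataset.omega
    orders, correlations, k_values = [], [], []
    for i in range(dataset.c):
        y = dataset.Y[:, i]
        order, r = rank_features(dataset.X, y, key=ranking)
        if isinstance(policy, FixedK):
            k = _clamp_k(policy.k, omega)
        elif isinstance(policy, FractionK):
            k = _clamp_k(max(1, round(policy.fraction * omega)), omega)
        elif isinstance(policy, InnerCVK):
            k = _cv_choose_k(dataset.X, y, policy, base_learner, ranking)
        else:
            raise TypeError(f"unknown K policy: {policy!r}")
        orders.append(order)
        correlations.append(r)
        k_values.append(k)
    return LabelSpecificSelection(
        orders=orders,
        correlations=correlations,
        k_values=k_values,
        labels=dataset.labelspace.labels,
    )
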