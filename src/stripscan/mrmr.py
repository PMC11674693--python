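"""Maximum-relevance minimum-redundancy feature ranking.

Greedy forward selection on mutual information after equal-frequency
discretisation: the first pick maximises I(f; label); each later pick
maximises I(f; label) - mean over already-selected s of I(f; s) (the
MI-difference criterion; the quotient variant is available).  Binning on
empirical quantiles makes the ranking invariant to strictly monotone
transforms of any feature.  Ties break toward the earlier column, so a
ranking is bitwise reproducible for fixed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted

__all__ = ["MRMRRanking", "rank_features", "select_top", "MRMRSelector"]


@dataclass
class MRMRRanking:
    """Feature names in selection order with their MRMR score at pick time."""

    names: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranked feature names must be unique")
        if len(self.scores) != len(self.names):
            raise ValueError("scores and names must align")


def _discretise(col: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning via empirical quantile edges."""
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, col, side="right")


def rank_features(
    table: pd.DataFrame | np.ndarray,
    labels,
    bins: int = 16,
    criterion: str = "mid",
) -> MRMRRanking:
    """Rank every feature column by greedy MRMR against ``labels``.

    A constant feature has zero mutual information with everything and sinks
    to the bottom; a single-class label vector is rejected.
    """
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        X = table.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(table, dtype=np.float64)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to rank")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; relevance is undefined")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    if criterion not in ("mid", "miq"):
        raise ValueError(f"unknown MRMR criterion {criterion!r}")

    n_feat = X.shape[1]
    disc = np.stack([_discretise(X[:, j], bins) for j in range(n_feat)], axis=1)
    relevance = np.array([mutual_info_score(y, disc[:, j]) for j in range(n_feat)])

    mi_ff = np.full((n_feat, n_feat), np.nan)
    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_feat))
    while remaining:
        if not selected:
            obj = relevance[remaining]
        else:
            red = np.empty(len(remaining))
            for r, j in enumerate(remaining):
                for s in selected:
                    if np.isnan(mi_ff[j, s]):
                        mi_ff[j, s] = mi_ff[s, j] = mutual_info_score(disc[:, j], disc[:, s])
                red[r] = np.mean(mi_ff[remaining[r], selected])
            if criterion == "mid":
                obj = relevance[remaining] - red
            else:
                obj = relevance[remaining] / (red + np.finfo(float).eps)
        best = int(np.argmax(obj))  # first max wins: ties break by column order
        scores.append(float(obj[best]))
        selected.append(remaining.pop(best))
    return MRMRRanking(names=[names[j] for j in selected], scores=scores)


def select_top(ranking: MRMRRanking, k: int = 9) -> list[str]:
    """First ``k`` names of a ranking, order preserved."""
    if not (1 <= k <= len(ranking.names)):
        raise ValueError(f"k={k} out of range 1..{len(ranking.names)}")
    return ranking.names[:k]


class MRMRSelector(SelectorMixin, BaseEstimator):
    """sklearn selector keeping the top-``k`` MRMR-ranked features.

    Fitted attributes: ``ranking_`` (an :class:`MRMRRanking`),
    ``support_mask_``.  Works in pipelines ahead of any classifier.
    """

    def __init__(self, k: int = 9, bins: int = 16, criterion: str = "mid"):
        self.k = k
        self.bins = bins
        self.criterion = criterion

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            arr = X.to_numpy(dtype=np.float64)
            names = [str(c) for c in X.columns]
        else:
            arr = np.asarray(X, dtype=np.float64)
            names = [f"f{i}" for i in range(arr.shape[1])]
        self.n_features_in_ = arr.shape[1]
        self.ranking_ = rank_features(
            pd.DataFrame(arr, columns=names), y, bins=self.bins, criterion=self.criterion
        )
        top = set(select_top(self.ranking_, self.k))
        self.support_mask_ = np.array([n in top for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def ranking_table(self) -> pd.DataFrame:
        check_is_fitted(self, "ranking_")
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking_.names) + 1),
                "feature": self.ranking_.names,
                "score": self.ranking_.scores,
            }
        )
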