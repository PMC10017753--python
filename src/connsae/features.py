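"""Min-max scaling and three-filter feature reduction to the top-k features.

The classifier consumes 60 of the 685 source topological features.  The
reduction combines three rankings computed on training rows only:

* Welch two-sample t-test, ranked by |t|;
* mutual information between each feature and the group label
  (k-nearest-neighbour estimator);
* Lasso, ranked by |coefficient| at an internally cross-validated penalty,
  with zero coefficients falling back to the t-test order.

The three ranks are averaged and the k features with the smallest mean rank
are selected (ties broken by feature index).  Scaling and selection are
always refit inside each cross-validation fold to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LassoCV
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "ScalerState",
    "SelectionResult",
    "minmax_fit",
    "minmax_apply",
    "rank_by_ttest",
    "rank_by_mutual_information",
    "rank_by_lasso",
    "select_top_features",
]


@dataclass
class ScalerState:
    """Per-feature min/max learned from training rows."""

    data_min: np.ndarray
    data_max: np.ndarray
    _scaler: MinMaxScaler


@dataclass
class SelectionResult:
    selected: list[int]
    ranks_ttest: np.ndarray
    ranks_mi: np.ndarray
    ranks_lasso: np.ndarray
    fold: int | None = None
    aggregate_rank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "selected": [int(i) for i in self.selected],
            "ranks_ttest": self.ranks_ttest.tolist(),
            "ranks_mi": self.ranks_mi.tolist(),
            "ranks_lasso": self.ranks_lasso.tolist(),
        }


def minmax_fit(X_train: np.ndarray) -> ScalerState:
    """Learn per-feature min and max from training rows only."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    scaler = MinMaxScaler(clip=True).fit(X_train)
    return ScalerState(data_min=scaler.data_min_.copy(),
                       data_max=scaler.data_max_.copy(), _scaler=scaler)


def minmax_apply(state: ScalerState, X: np.ndarray) -> np.ndarray:
    """Scale rows to [0, 1] with the learned bounds; out-of-range values clip.

    Features constant in training map to 0.
    """
    X = np.asarray(X, dtype=float)
    return state._scaler.transform(X)


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("exactly two classes required")
    return y


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank vector: 0 for the most discriminative feature, ties by index.

    ``scores`` are 'larger = better'; NaNs rank last.
    """
    scores = np.where(np.isnan(scores), -np.inf, scores)
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=float)
    ranks[order] = np.arange(len(scores))
    return ranks


def _abs_welch_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(X[y == classes[0]], X[y == classes[1]],
                               axis=0, equal_var=False)
    return np.abs(np.asarray(t, dtype=float))


def rank_by_ttest(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature rank by |Welch t| between the two classes (0 = best)."""
    X = np.asarray(X, dtype=float)
    _check_two_classes(y)
    return _scores_to_ranks(_abs_welch_t(X, y))


def rank_by_mutual_information(X: np.ndarray, y: np.ndarray,
                               seed: int = 0, n_neighbors: int = 3) -> np.ndarray:
    """Per-feature rank by estimated mutual information with the label."""
    X = np.asarray(X, dtype=float)
    _check_two_classes(y)
    mi = mutual_info_classif(X, y, n_neighbors=n_neighbors, random_state=seed)
    return _scores_to_ranks(mi)


def rank_by_lasso(X: np.ndarray, y: np.ndarray, seed: int = 0,
                  n_alphas: int = 30) -> np.ndarray:
    """Per-feature rank by |Lasso coefficient| at a cross-validated penalty.

    The binary label is regressed as 0/1.  Features with exactly zero
    coefficients are ranked after all non-zero ones, ordered among
    themselves by the t-test criterion.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y)
    y01 = (y == np.unique(y)[1]).astype(float)
    # standardize so the penalty treats features symmetrically
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    lasso = LassoCV(cv=5, alphas=n_alphas, random_state=seed,
                    max_iter=5000).fit(Xs, y01)
    coefs = np.abs(lasso.coef_)
    tfall = _abs_welch_t(X, y)
    tfall = np.where(np.isnan(tfall), -np.inf, tfall)
    nonzero = coefs > 0
    order_nonzero = np.flatnonzero(nonzero)[
        np.argsort(-coefs[nonzero], kind="stable")]
    order_zero = np.flatnonzero(~nonzero)[
        np.argsort(-tfall[~nonzero], kind="stable")]
    ranks = np.empty(X.shape[1], dtype=float)
    ranks[np.concatenate([order_nonzero, order_zero])] = np.arange(X.shape[1])
    return ranks


def select_top_features(ranks_t: np.ndarray, ranks_mi: np.ndarray,
                        ranks_lasso: np.ndarray, k: int = 60,
                        fold: int | None = None) -> SelectionResult:
    """Mean-rank aggregation of the three filter methods; keep the top k."""
    ranks_t = np.asarray(ranks_t, dtype=float)
    ranks_mi = np.asarray(ranks_mi, dtype=float)
    ranks_lasso = np.asarray(ranks_lasso, dtype=float)
    if not (len(ranks_t) == len(ranks_mi) == len(ranks_lasso)):
        raise ValueError("rank vectors must have equal length")
    if k > len(ranks_t):
        raise ValueError(f"k={k} exceeds feature count {len(ranks_t)}")
    agg = (ranks_t + ranks_mi + ranks_lasso) / 3.0
    order = np.argsort(agg, kind="stable")  # ties broken by feature index
    selected = order[:k].tolist()
    return SelectionResult(selected=selected, ranks_ttest=ranks_t,
                           ranks_mi=ranks_mi, ranks_lasso=ranks_lasso,
                           fold=fold, aggregate_rank=agg)


def rank_and_select(X_train: np.ndarray, y_train: np.ndarray, k: int = 60,
                    seed: int = 0, fold: int | None = None) -> SelectionResult:
    """Convenience: run all three ranking methods and select the top k."""
    rt = rank_by_ttest(X_train, y_train)
    rmi = rank_by_mutual_information(X_train, y_train, seed=seed)
    rl = rank_by_lasso(X_train, y_train, seed=seed)
    return select_top_features(rt, rmi, rl, k=k, fold=fold)
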