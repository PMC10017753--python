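"""Permutation-based feature importance for the trained classifier.

A feature's importance is the mean squared change in classification
cross-entropy when its column is shuffled across subjects:

    FI = (1/m) * sum_k (H - H'_k)^2

with ``H`` the cross-entropy of the intact input (fixed baseline) and
``H'_k`` the cross-entropy after the k-th independent shuffle of that
column.  Features scoring more than two standard deviations above the mean
importance of all features are flagged as important.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssae import CVResult, TrainedSSAE, binary_cross_entropy_loss, predict

__all__ = [
    "ImportanceResult",
    "permutation_importance",
    "identify_important_features",
    "cv_permutation_importance",
]


@dataclass
class ImportanceResult:
    scores: np.ndarray
    n_shuffles: int
    seed: int | None
    selected: list[int]
    score_mean: float
    score_sd: float
    fold: int | None = None

    def to_dict(self) -> dict:
        return {"scores": self.scores.tolist(), "n_shuffles": self.n_shuffles,
                "seed": self.seed, "selected": self.selected,
                "score_mean": self.score_mean, "score_sd": self.score_sd,
                "fold": self.fold}


def permutation_importance(model: TrainedSSAE, X: np.ndarray, y: np.ndarray,
                           m: int = 1000, seed: int | None = 0,
                           fold: int | None = None,
                           permutations: np.ndarray | None = None
                           ) -> ImportanceResult:
    """FI score per feature from m independent column shuffles.

    ``X`` must be scaled exactly as at training time.  Shuffles are plain
    permutations (a shuffle may coincide with the identity); the baseline
    cross-entropy is computed once on the intact input.  ``permutations``
    (an (m, n) array of row orderings applied to every feature in turn)
    overrides the random draws, e.g. to enumerate all n! shuffles exactly.
    """
    if permutations is not None:
        permutations = np.asarray(permutations)
        m = permutations.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n, n_feat = X.shape
    H = binary_cross_entropy_loss(y, predict(model, X))
    scores = np.empty(n_feat)
    for j in range(n_feat):
        # m permutations of the column, evaluated in one stacked forward pass
        perms = (permutations if permutations is not None
                 else np.argsort(rng.random((m, n)), axis=1))
        Xrep = np.broadcast_to(X, (m, n, n_feat)).copy()
        Xrep[:, :, j] = X[perms[:, :], j]
        p = predict(model, Xrep.reshape(m * n, n_feat)).reshape(m, n)
        pc = np.clip(p, 1e-7, 1 - 1e-7)
        H_shuf = -(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean(axis=1)
        scores[j] = ((H - H_shuf) ** 2).mean()
    selected = identify_important_features(scores)
    return ImportanceResult(scores=scores, n_shuffles=m, seed=seed,
                            selected=selected,
                            score_mean=float(scores.mean()),
                            score_sd=float(scores.std()), fold=fold)


def identify_important_features(scores: np.ndarray, n_sd: float = 2.0,
                                ddof: int = 0) -> list[int]:
    """Indices of scores strictly above mean + n_sd * SD (population SD).

    With all scores equal the SD is zero and the strict inequality yields an
    empty selection.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    threshold = scores.mean() + n_sd * scores.std(ddof=ddof)
    return np.flatnonzero(scores > threshold).tolist()


def cv_permutation_importance(cv: CVResult, X: np.ndarray, y: np.ndarray,
                              n_source_features: int, m: int = 1000,
                              seed: int = 0) -> tuple[np.ndarray, list[ImportanceResult]]:
    """Fold-averaged FI in source-feature space.

    For each fold, importance is computed on that fold's validation rows with
    that fold's model (and its scaler/selection); per-fold scores are mapped
    back to the source-feature indices and averaged over the folds in which a
    feature was selected (NaN elsewhere).  Returns (mean scores, per-fold
    results).
    """
    from .features import minmax_apply  # local import to avoid cycle noise

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    per_fold = np.full((len(cv.models), n_source_features), np.nan)
    results: list[ImportanceResult] = []
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(len(cv.models))]
    for f, (model, scaler, sel) in enumerate(
            zip(cv.models, cv.scalers, cv.selections)):
        _, va = cv.fold_indices[f]
        Xva = minmax_apply(scaler, X[va])
        cols = sel.selected if sel is not None else list(range(X.shape[1]))
        res = permutation_importance(model, Xva[:, cols], y[va], m=m,
                                     seed=seeds[f], fold=f)
        results.append(res)
        per_fold[f, cols] = res.scores
    counts = (~np.isnan(per_fold)).sum(axis=0)
    sums = np.nansum(per_fold, axis=0)
    mean_scores = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean_scores, results
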