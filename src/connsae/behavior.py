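"""Brain-behaviour analyses linking important features to symptom scores.

Three analyses mirror the post-hoc workflow after classification:

1. `fit_svr_cv`: cross-validated support vector regression predicting a
   Conners T-score from the important topological features, scored by
   out-of-sample R^2 and MSE on min-max-scaled targets, with a
   permutation-importance analogue for the regressor.
2. `correlate_latents`: Pearson correlation of each latent AE-feature with a
   T-score, Bonferroni-corrected over the latent dimensions.
3. `fit_path_model`: a two-layer path analysis (brain features -> each
   selected latent; latents + covariates -> T-score) on standardized
   variables, estimated by least squares.  Because every construct is a
   single measured variable, PLS-style structural modeling reduces exactly
   to this standardized regression form.  Significance comes from bootstrap
   resampling of subjects (percentile sign test on the coefficient's
   bootstrap distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .features import minmax_apply, minmax_fit

__all__ = [
    "RegressionResult",
    "PathModelResult",
    "fit_svr_cv",
    "svr_permutation_importance",
    "correlate_latents",
    "fit_path_model",
]

logger = logging.getLogger(__name__)

# Epsilon-insensitive tube width for SVR on targets scaled to [0, 1];
# libsvm's default 0.1 would ignore errors up to 10% of the target range.
_SVR_EPSILON = 0.01


@dataclass
class RegressionResult:
    r2_per_fold: np.ndarray
    mse_per_fold: np.ndarray
    predictions: pd.DataFrame  # columns: fold, observed, predicted (T-score scale)
    importance: np.ndarray | None = None

    @property
    def r2_mean(self) -> float:
        return float(self.r2_per_fold.mean())

    @property
    def r2_sd(self) -> float:
        return float(self.r2_per_fold.std(ddof=1))

    @property
    def mse_mean(self) -> float:
        return float(self.mse_per_fold.mean())

    @property
    def mse_sd(self) -> float:
        return float(self.mse_per_fold.std(ddof=1))

    def to_dict(self) -> dict:
        d = {"r2": {"per_fold": self.r2_per_fold.tolist(),
                    "mean": self.r2_mean, "sd": self.r2_sd},
             "mse": {"per_fold": self.mse_per_fold.tolist(),
                     "mean": self.mse_mean, "sd": self.mse_sd}}
        if self.importance is not None:
            d["feature_importance"] = self.importance.tolist()
        return d


@dataclass
class PathModelResult:
    feature_to_latent: pd.DataFrame  # columns: latent, feature, coef, p
    latent_to_outcome: pd.DataFrame  # columns: predictor, coef, p
    n_boot: int
    dropped_covariates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"feature_to_latent": self.feature_to_latent.to_dict("records"),
                "latent_to_outcome": self.latent_to_outcome.to_dict("records"),
                "n_boot": self.n_boot,
                "dropped_covariates": self.dropped_covariates}


def _scale_target(t_train: np.ndarray, t: np.ndarray
                  ) -> tuple[np.ndarray, float, float]:
    lo, hi = float(t_train.min()), float(t_train.max())
    span = hi - lo
    return (t - lo) / span, lo, span


def fit_svr_cv(X_top: np.ndarray, t: np.ndarray, k: int = 5,
               seed: int = 0, m_importance: int | None = None
               ) -> RegressionResult:
    """k-fold cross-validated RBF support vector regression.

    Features and targets are min-max scaled inside each training fold;
    out-of-sample R^2 is ``1 - SSE/SST`` with SST taken about the validation
    fold's own mean, and MSE is reported on the scaled target.  Predictions
    are returned back on the T-score scale.  When ``m_importance`` is set, a
    permutation importance (squared MSE-difference form) is computed on the
    full sample with a model refit on all rows.
    """
    X = np.atleast_2d(np.asarray(X_top, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if np.ptp(t) == 0:
        raise ValueError("target is constant")
    folds = KFold(n_splits=k, shuffle=True, random_state=int(seed)).split(X)
    r2s, mses, rows = [], [], []
    for f, (tr, va) in enumerate(folds):
        scaler = minmax_fit(X[tr])
        Xtr, Xva = minmax_apply(scaler, X[tr]), minmax_apply(scaler, X[va])
        ts_all, lo, span = _scale_target(t[tr], t)
        svr = SVR(kernel="rbf", epsilon=_SVR_EPSILON).fit(Xtr, ts_all[tr])
        pred_s = svr.predict(Xva)
        resid = ts_all[va] - pred_s
        sse = float((resid ** 2).sum())
        sst = float(((ts_all[va] - ts_all[va].mean()) ** 2).sum())
        r2s.append(1.0 - sse / sst if sst > 0 else 0.0)
        mses.append(float((resid ** 2).mean()))
        for obs, pr in zip(t[va], pred_s * span + lo):
            rows.append({"fold": f, "observed": obs, "predicted": pr})
    importance = None
    if m_importance:
        scaler = minmax_fit(X)
        Xs = minmax_apply(scaler, X)
        ts, _, _ = _scale_target(t, t)
        model = SVR(kernel="rbf", epsilon=_SVR_EPSILON).fit(Xs, ts)
        importance = svr_permutation_importance(model, Xs, ts,
                                                m=m_importance, seed=seed)
    return RegressionResult(r2_per_fold=np.array(r2s),
                            mse_per_fold=np.array(mses),
                            predictions=pd.DataFrame(rows),
                            importance=importance)


def svr_permutation_importance(model, X: np.ndarray, t: np.ndarray,
                               m: int = 1000, seed: int = 0) -> np.ndarray:
    """Regression analogue of the classification FI score.

    ``FI_j = (1/m) sum_k (MSE - MSE'_k)^2`` where MSE' is the model's error
    after the k-th shuffle of feature j.  Inputs must be scaled exactly as
    at fit time.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    base_mse = float(((model.predict(X) - t) ** 2).mean())
    n = X.shape[0]
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        diffs = np.empty(m)
        for kk in range(m):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(n), j]
            mse = float(((model.predict(Xp) - t) ** 2).mean())
            diffs[kk] = (base_mse - mse) ** 2
        scores[j] = diffs.mean()
    return scores


def correlate_latents(latents: np.ndarray, t: np.ndarray,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of each latent AE-feature with the T-score, Bonferroni-corrected.

    Returns a DataFrame with columns (latent, r, p_raw, p_bonferroni,
    significant); zero-variance latents get r = NaN and are never flagged.
    The correction factor is the number of latent dimensions.
    """
    Z = np.atleast_2d(np.asarray(latents, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n_lat = Z.shape[1]
    rows = []
    for j in range(n_lat):
        z = Z[:, j]
        if z.std() == 0 or t.std() == 0:
            r, p = np.nan, 1.0
        else:
            r, p = stats.pearsonr(z, t)
        p_b = min(1.0, n_lat * p)
        rows.append({"latent": j, "r": r, "p_raw": p, "p_bonferroni": p_b,
                     "significant": bool(p_b < alpha)})
    return pd.DataFrame(rows)


def _standardize_frame(df: pd.DataFrame, warn: bool = True
                       ) -> tuple[pd.DataFrame, list[str]]:
    dropped = [c for c in df.columns if df[c].std(ddof=0) == 0]
    if dropped and warn:
        logger.warning("dropping zero-variance columns: %s", dropped)
    kept = df.drop(columns=dropped)
    return (kept - kept.mean()) / kept.std(ddof=0), dropped


def _check_collinearity(X: pd.DataFrame) -> None:
    if X.shape[1] < 2:
        return
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    iu = np.triu_indices(corr.shape[0], k=1)
    bad = np.abs(corr[iu]) > 1 - 1e-10
    if bad.any():
        pairs = [(X.columns[iu[0][i]], X.columns[iu[1][i]])
                 for i in np.flatnonzero(bad)]
        raise ValueError(f"collinear predictors: {pairs}")


def _ols_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return beta[1:]


def _boot_p(boot: np.ndarray) -> float:
    lo = float((boot <= 0).mean())
    hi = float((boot >= 0).mean())
    return min(1.0, 2.0 * min(lo, hi))


def fit_path_model(features_important: pd.DataFrame,
                   latents_selected: pd.DataFrame,
                   t: np.ndarray,
                   covariates: pd.DataFrame | None = None,
                   n_boot: int = 5000, seed: int = 0) -> PathModelResult:
    """Two-layer standardized path analysis with bootstrap p-values.

    Layer 1 regresses each selected latent on the important brain features;
    layer 2 regresses the T-score on the latents plus covariates (age, sex,
    SES, IQ, ...).  All variables are standardized within each (re)sample, so
    coefficients are standardized path weights; a single feature predicting a
    single latent reduces to their Pearson r.  Zero-variance covariates (for
    example handedness in an all-right-handed cohort) are dropped with a
    warning.  p-values are two-sided bootstrap sign tests over ``n_boot``
    subject resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    F = pd.DataFrame(features_important).reset_index(drop=True)
    Z = pd.DataFrame(latents_selected).reset_index(drop=True)
    t = np.asarray(t, dtype=float).ravel()
    cov = (pd.DataFrame(covariates).reset_index(drop=True)
           if covariates is not None else pd.DataFrame(index=range(len(t))))
    # zero-variance covariates (e.g. handedness in an all-right-handed
    # cohort) cannot be standardized; drop them once, with a warning
    _, dropped_init = _standardize_frame(cov)
    cov = cov.drop(columns=dropped_init)
    n = len(t)

    def estimate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, list, list]:
        Fs, _ = _standardize_frame(F.iloc[idx], warn=False)
        Zs, _ = _standardize_frame(Z.iloc[idx], warn=False)
        Cs, drop = _standardize_frame(cov.iloc[idx], warn=False)
        ts = stats.zscore(t[idx])
        l1 = np.column_stack([_ols_coefs(Fs.to_numpy(), Zs[c].to_numpy())
                              for c in Zs.columns]) if len(Zs.columns) else np.empty((F.shape[1], 0))
        X2 = pd.concat([Zs, Cs], axis=1)
        l2 = _ols_coefs(X2.to_numpy(), ts)
        return l1, l2, list(X2.columns), drop

    full_idx = np.arange(n)
    _check_collinearity(pd.concat(
        [_standardize_frame(F)[0], _standardize_frame(Z)[0],
         _standardize_frame(cov)[0]], axis=1))
    l1_hat, l2_hat, l2_names, _ = estimate(full_idx)

    rng = np.random.default_rng(seed)
    boots1 = np.empty((n_boot,) + l1_hat.shape)
    boots2 = np.empty((n_boot,) + l2_hat.shape)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            b1, b2, _, _ = estimate(idx)
            if b1.shape != l1_hat.shape or b2.shape != l2_hat.shape:
                raise ValueError("degenerate resample")
        except (ValueError, KeyError):  # e.g. a column constant in the resample
            b1, b2 = l1_hat, l2_hat
        boots1[b] = b1
        boots2[b] = b2

    rows1 = []
    for ci, lat in enumerate(Z.columns):
        for fi, feat in enumerate(F.columns):
            rows1.append({"latent": lat, "feature": feat,
                          "coef": float(l1_hat[fi, ci]),
                          "p": _boot_p(boots1[:, fi, ci])})
    rows2 = [{"predictor": name, "coef": float(l2_hat[i]),
              "p": _boot_p(boots2[:, i])}
             for i, name in enumerate(l2_names)]
    return PathModelResult(feature_to_latent=pd.DataFrame(rows1),
                           latent_to_outcome=pd.DataFrame(rows2),
                           n_boot=n_boot, dropped_covariates=dropped_init)
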