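"""Semi-supervised autoencoder for group classification of brain features.

The model couples a standard autoencoder (encoder 60-40-20, decoder
20-40-60) with a classification head (20-20-1) read off the 20-dimensional
latent code (the "AE-features").  Every neuron is a sigmoid unit.  Training
minimises the composite loss

    L = 0.7 * MSE(reconstruction) + 0.3 * BCE(classification),

so the latent code is shaped primarily by reconstruction and constrained by
the supervised head.  Optimisation is full-batch Adam with hand-written
backpropagation (the networks are tiny, n <= a few hundred); training stops
when clean-input training accuracy exceeds 95% or at 1000 epochs.  As an
augmentation, Gaussian noise (sd 0.02) is injected into a random 20% of
input entries, re-sampled every epoch; reconstruction targets stay clean.

`cross_validate_ssae` runs the stratified five-fold protocol with min-max
scaling and three-filter feature selection refit inside every fold, and
`pca_svm_baseline` evaluates a PCA+SVM model under the identical protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import ScalerState, SelectionResult, minmax_apply, minmax_fit, rank_and_select

__all__ = [
    "AEConfig",
    "TrainedSSAE",
    "CVResult",
    "mse_reconstruction_loss",
    "binary_cross_entropy_loss",
    "combined_loss",
    "inject_gaussian_noise",
    "train_ssae",
    "predict",
    "encode",
    "cross_validate_ssae",
    "pca_svm_baseline",
]

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class AEConfig:
    encoder_sizes: tuple[int, ...] = (60, 40, 20)
    decoder_sizes: tuple[int, ...] = (20, 40, 60)
    classifier_sizes: tuple[int, ...] = (20, 20, 1)
    decoder_loss_weight: float = 0.7
    classifier_loss_weight: float = 0.3
    noise_std: float = 0.02
    noise_fraction: float = 0.20
    max_epochs: int = 1000
    train_accuracy_stop: float = 0.95
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.decoder_loss_weight + self.classifier_loss_weight - 1.0) > 1e-12:
            raise ValueError("loss weights must sum to 1")
        if self.decoder_sizes[0] != self.encoder_sizes[-1]:
            raise ValueError("decoder input must equal latent size")
        if self.classifier_sizes[0] != self.encoder_sizes[-1]:
            raise ValueError("classifier input must equal latent size")
        if self.decoder_sizes[-1] != self.encoder_sizes[0]:
            raise ValueError("decoder output must equal encoder input")
        if self.classifier_sizes[-1] != 1:
            raise ValueError("classifier must end in a single output neuron")
        if not (0 <= self.noise_fraction <= 1) or self.noise_std < 0:
            raise ValueError("invalid noise parameters")

    @property
    def input_dim(self) -> int:
        return self.encoder_sizes[0]

    @property
    def latent_dim(self) -> int:
        return self.encoder_sizes[-1]


@dataclass
class TrainedSSAE:
    config: AEConfig
    params: dict[str, np.ndarray]
    history: dict[str, list[float]]
    stop_reason: str
    n_epochs: int

    def encode(self, X: np.ndarray) -> np.ndarray:
        return encode(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return _forward(self.params, _check_width(X, self.config.input_dim))["xr"]

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))

    def save(self, path) -> None:
        """Portable JSON checkpoint (architecture + parameters + history)."""
        import json
        payload = {
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in self.config.__dict__.items()},
            "params": {k: v.tolist() for k, v in self.params.items()},
            "history": self.history,
            "stop_reason": self.stop_reason,
            "n_epochs": self.n_epochs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedSSAE":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        cfg_raw = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in payload["config"].items()}
        return cls(config=AEConfig(**cfg_raw),
                   params={k: np.asarray(v)
                           for k, v in payload["params"].items()},
                   history=payload["history"],
                   stop_reason=payload["stop_reason"],
                   n_epochs=payload["n_epochs"])


@dataclass
class CVResult:
    """Per-fold metrics and artefacts of a k-fold cross-validated model."""

    accuracies: np.ndarray
    aucs: np.ndarray
    recon_mses: np.ndarray
    fold_assignments: np.ndarray
    fold_indices: list[tuple[np.ndarray, np.ndarray]]
    models: list
    scalers: list[ScalerState]
    selections: list[SelectionResult | None]
    predictions: list[tuple[np.ndarray, np.ndarray]]  # (y_val, p_val) per fold
    stop_reasons: list[str] = field(default_factory=list)

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.accuracies.std(ddof=1))

    @property
    def auc_mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.aucs.std(ddof=1))

    @property
    def recon_mse_mean(self) -> float:
        return float(self.recon_mses.mean())

    @property
    def recon_mse_sd(self) -> float:
        return float(self.recon_mses.std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "accuracy": {"per_fold": self.accuracies.tolist(),
                         "mean": self.accuracy_mean, "sd": self.accuracy_sd},
            "auc": {"per_fold": self.aucs.tolist(),
                    "mean": self.auc_mean, "sd": self.auc_sd},
            "reconstruction_mse": {"per_fold": self.recon_mses.tolist(),
                                   "mean": self.recon_mse_mean,
                                   "sd": self.recon_mse_sd},
            "stop_reasons": list(self.stop_reasons),
        }


def mse_reconstruction_loss(X: np.ndarray, X_reconstructed: np.ndarray) -> float:
    """Mean over subjects of the mean-over-features squared error."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xr = np.atleast_2d(np.asarray(X_reconstructed, dtype=float))
    if X.shape != Xr.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xr.shape}")
    return float(((Xr - X) ** 2).mean(axis=1).mean())


def binary_cross_entropy_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.clip(np.asarray(p, dtype=float).ravel(), _BCE_EPS, 1 - _BCE_EPS)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def combined_loss(mse: float, h_binary: float,
                  decoder_weight: float = 0.7,
                  classifier_weight: float = 0.3) -> float:
    """Composite full-model loss: 0.7*MSE + 0.3*BCE by default."""
    return decoder_weight * mse + classifier_weight * h_binary


def inject_gaussian_noise(X: np.ndarray, fraction: float = 0.20,
                          std: float = 0.02,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Perturb a Bernoulli(fraction) subset of entries with N(0, std^2)."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if std < 0:
        raise ValueError("std must be >= 0")
    X = np.asarray(X, dtype=float)
    if fraction == 0 or std == 0:
        return X.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(X.shape) < fraction
    noise = rng.normal(0.0, std, size=X.shape)
    return X + mask * noise


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


_LAYER_KEYS = ("e1", "e2", "d1", "d2", "c1", "c2")


def _layer_shapes(config: AEConfig) -> dict[str, tuple[int, int]]:
    e, d, c = config.encoder_sizes, config.decoder_sizes, config.classifier_sizes
    return {"e1": (e[0], e[1]), "e2": (e[1], e[2]),
            "d1": (d[0], d[1]), "d2": (d[1], d[2]),
            "c1": (c[0], c[1]), "c2": (c[1], c[2])}


def _init_params(config: AEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    for key, (fan_in, fan_out) in _layer_shapes(config).items():
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        params[f"W_{key}"] = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        params[f"b_{key}"] = np.zeros(fan_out)
    return params


def _forward_classifier(params: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Probability head only (skips the decoder)."""
    h1 = _sigmoid(X @ params["W_e1"] + params["b_e1"])
    z = _sigmoid(h1 @ params["W_e2"] + params["b_e2"])
    q1 = _sigmoid(z @ params["W_c1"] + params["b_c1"])
    return _sigmoid(q1 @ params["W_c2"] + params["b_c2"]).ravel()


def _forward(params: dict[str, np.ndarray], X: np.ndarray) -> dict[str, np.ndarray]:
    h1 = _sigmoid(X @ params["W_e1"] + params["b_e1"])
    z = _sigmoid(h1 @ params["W_e2"] + params["b_e2"])
    g1 = _sigmoid(z @ params["W_d1"] + params["b_d1"])
    xr = _sigmoid(g1 @ params["W_d2"] + params["b_d2"])
    q1 = _sigmoid(z @ params["W_c1"] + params["b_c1"])
    p = _sigmoid(q1 @ params["W_c2"] + params["b_c2"]).ravel()
    return {"h1": h1, "z": z, "g1": g1, "xr": xr, "q1": q1, "p": p}


def _backward(params: dict[str, np.ndarray], X_in: np.ndarray,
              X_target: np.ndarray, y: np.ndarray,
              acts: dict[str, np.ndarray], wd: float, wc: float
              ) -> dict[str, np.ndarray]:
    n, f = X_target.shape
    h1, z, g1, xr, q1, p = (acts[k] for k in ("h1", "z", "g1", "xr", "q1", "p"))
    grads: dict[str, np.ndarray] = {}
    # decoder head: d MSE / d a = 2(xr-x)/(n f) * xr(1-xr), weighted wd
    ga_d2 = wd * (2.0 / (n * f)) * (xr - X_target) * xr * (1 - xr)
    grads["W_d2"] = g1.T @ ga_d2
    grads["b_d2"] = ga_d2.sum(axis=0)
    ga_d1 = (ga_d2 @ params["W_d2"].T) * g1 * (1 - g1)
    grads["W_d1"] = z.T @ ga_d1
    grads["b_d1"] = ga_d1.sum(axis=0)
    # classifier head: d BCE / d a = (p-y)/n through the sigmoid, weighted wc
    ga_c2 = (wc * (p - y) / n)[:, None]
    grads["W_c2"] = q1.T @ ga_c2
    grads["b_c2"] = ga_c2.sum(axis=0)
    ga_c1 = (ga_c2 @ params["W_c2"].T) * q1 * (1 - q1)
    grads["W_c1"] = z.T @ ga_c1
    grads["b_c1"] = ga_c1.sum(axis=0)
    # shared encoder
    gz = ga_d1 @ params["W_d1"].T + ga_c1 @ params["W_c1"].T
    ga_e2 = gz * z * (1 - z)
    grads["W_e2"] = h1.T @ ga_e2
    grads["b_e2"] = ga_e2.sum(axis=0)
    ga_e1 = (ga_e2 @ params["W_e2"].T) * h1 * (1 - h1)
    grads["W_e1"] = X_in.T @ ga_e1
    grads["b_e1"] = ga_e1.sum(axis=0)
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _check_width(X: np.ndarray, width: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != width:
        raise ValueError(f"expected {width} features, got {X.shape[1]}")
    return X


def train_ssae(X_train: np.ndarray, y_train: np.ndarray,
               config: AEConfig) -> TrainedSSAE:
    """Train the semi-supervised autoencoder on (scaled) training data.

    Deterministic given ``config.seed``: initialisation and per-epoch noise
    masks come from one seeded generator.  Raises on non-finite loss.
    """
    X = _check_width(X_train, config.input_dim)
    y = np.asarray(y_train, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("X and y row counts differ")
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    opt = _Adam(params, config.learning_rate)
    wd, wc = config.decoder_loss_weight, config.classifier_loss_weight
    history: dict[str, list[float]] = {"loss": [], "mse": [], "bce": [],
                                       "train_accuracy": []}
    stop_reason = "max_epochs"
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        Xn = inject_gaussian_noise(X, config.noise_fraction, config.noise_std, rng)
        acts = _forward(params, Xn)
        mse = mse_reconstruction_loss(X, acts["xr"])
        bce = binary_cross_entropy_loss(y, acts["p"])
        loss = combined_loss(mse, bce, wd, wc)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: mse={mse}, bce={bce}")
        grads = _backward(params, Xn, X, y, acts, wd, wc)
        opt.step(params, grads)
        # stopping accuracy is evaluated on clean inputs
        p_clean = _forward_classifier(params, X)
        acc = float(((p_clean >= 0.5).astype(float) == y).mean())
        history["loss"].append(loss)
        history["mse"].append(mse)
        history["bce"].append(bce)
        history["train_accuracy"].append(acc)
        if acc > config.train_accuracy_stop:
            stop_reason = "accuracy"
            break
    return TrainedSSAE(config=config, params=params, history=history,
                       stop_reason=stop_reason, n_epochs=epoch)


def predict(model: TrainedSSAE, X: np.ndarray) -> np.ndarray:
    """Class-1 (TBI) probability per row."""
    X = _check_width(X, model.config.input_dim)
    return _forward_classifier(model.params, X)


def encode(model: TrainedSSAE, X: np.ndarray) -> np.ndarray:
    """Latent AE-features (latent_dim per row)."""
    X = _check_width(X, model.config.input_dim)
    return _forward(model.params, X)["z"]


def _stratified_folds(y: np.ndarray, k: int, seed: int
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    y = np.asarray(y)
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < k:
            raise ValueError(f"class {cls} has {cnt} < k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(y)), y)]


def cross_validate_ssae(X: np.ndarray, y: np.ndarray, config: AEConfig,
                        k: int = 5, n_select: int | None = None,
                        seed: int | None = None) -> CVResult:
    """Stratified k-fold evaluation with in-fold scaling and selection.

    ``X`` holds the source features (unscaled).  When X has more columns
    than the encoder input, the three-filter reduction to
    ``n_select`` (default: encoder input size) runs inside each fold on
    training rows only; min-max scaling is likewise refit per fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    cv_seed = int(seed if seed is not None else config.seed)
    n_select = n_select or config.input_dim
    folds = _stratified_folds(y, k, cv_seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31))
                  for s in np.random.SeedSequence(cv_seed).spawn(k)]
    accs, aucs, mses = [], [], []
    models, scalers, selections, preds, stops = [], [], [], [], []
    assign = np.empty(len(y), dtype=int)
    for f, (tr, va) in enumerate(folds):
        assign[va] = f
        scaler = minmax_fit(X[tr])
        Xtr = minmax_apply(scaler, X[tr])
        Xva = minmax_apply(scaler, X[va])
        if X.shape[1] > config.input_dim:
            sel = rank_and_select(Xtr, y[tr], k=n_select, seed=fold_seeds[f], fold=f)
            cols = sel.selected
            Xtr, Xva = Xtr[:, cols], Xva[:, cols]
        else:
            sel = None
        fold_config = AEConfig(**{**config.__dict__, "seed": fold_seeds[f]})
        model = train_ssae(Xtr, y[tr], fold_config)
        p = predict(model, Xva)
        accs.append(float(((p >= 0.5).astype(float) == y[va]).mean()))
        aucs.append(float(roc_auc_score(y[va], p)))
        mses.append(mse_reconstruction_loss(Xva, model.reconstruct(Xva)))
        models.append(model)
        scalers.append(scaler)
        selections.append(sel)
        preds.append((y[va].copy(), p))
        stops.append(model.stop_reason)
    return CVResult(accuracies=np.array(accs), aucs=np.array(aucs),
                    recon_mses=np.array(mses), fold_assignments=assign,
                    fold_indices=folds, models=models, scalers=scalers,
                    selections=selections, predictions=preds,
                    stop_reasons=stops)


def pca_svm_baseline(X: np.ndarray, y: np.ndarray, k: int = 5,
                     n_components: float | int = 0.95,
                     seed: int = 0) -> CVResult:
    """PCA feature reduction + RBF-SVM classifier under the same CV protocol.

    Fold assignments are identical to `cross_validate_ssae` for the same
    seed, enabling a head-to-head comparison.  The reconstruction MSE is the
    PCA round-trip error on validation rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    folds = _stratified_folds(y, k, int(seed))
    accs, aucs, mses = [], [], []
    models, scalers, preds = [], [], []
    assign = np.empty(len(y), dtype=int)
    for f, (tr, va) in enumerate(folds):
        assign[va] = f
        scaler = minmax_fit(X[tr])
        Xtr = minmax_apply(scaler, X[tr])
        Xva = minmax_apply(scaler, X[va])
        pca = PCA(n_components=n_components, svd_solver="full").fit(Xtr)
        Ztr, Zva = pca.transform(Xtr), pca.transform(Xva)
        svm = SVC(kernel="rbf").fit(Ztr, y[tr])
        score = svm.decision_function(Zva)
        accs.append(float((svm.predict(Zva) == y[va]).mean()))
        aucs.append(float(roc_auc_score(y[va], score)))
        mses.append(mse_reconstruction_loss(Xva, pca.inverse_transform(Zva)))
        models.append((pca, svm))
        scalers.append(scaler)
        preds.append((y[va].copy(), score))
    return CVResult(accuracies=np.array(accs), aucs=np.array(aucs),
                    recon_mses=np.array(mses), fold_assignments=assign,
                    fold_indices=folds, models=models, scalers=scalers,
                    selections=[None] * k, predictions=preds,
                    stop_reasons=["n/a"] * k)
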