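"""Classifiers over ensemble docking features: LDA, QDA and a small MLP.

Three model families map the six-feature vectors to an activity probability:

* **LDA** — Gaussian classes with a pooled covariance; linear boundary.
* **QDA** — per-class covariances; quadratic boundary.
* **MLP** — 6 → 16 → 16 → 1 with sigmoid activations, batch normalisation
  between the hidden layers and before the output, trained with RMSProp on
  binary cross-entropy (batch size 64, 2000 epochs by default).

Splitting is a seeded random partition; cross-validation is stratified
five-fold with the feature scaler re-fitted inside every fold so no test
statistics leak into training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold, KFold

from .ensemble_features import Scaler, fit_scaler

__all__ = [
    "SplitSpec",
    "MlpConfig",
    "TrainedClassifier",
    "ModelError",
    "TrainingDivergedError",
    "split_dataset",
    "train_discriminant",
    "train_mlp",
    "fit_classifier",
    "cross_validate",
    "predict_proba",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

N_FEATURES = 6


class ModelError(ValueError):
    pass


class TrainingDivergedError(ModelError):
    """MLP loss became non-finite; carries the epoch where it happened."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        super().__init__(f"non-finite loss ({loss}) at epoch {epoch}")


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random train/test partition; train size = round(n·fraction)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify: bool = False

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ModelError(
                f"train_fraction must be in (0,1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class MlpConfig:
    """Architecture and optimiser settings for the perceptron."""

    hidden: tuple[int, int] = (16, 16)
    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int = 64
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-8
    bn_momentum: float = 0.99
    seed: int = 0


def split_dataset(records: Sequence, spec: SplitSpec,
                  labels: Sequence[int] | None = None):
    """Deterministic random partition into (train, test) lists.

    With ``spec.stratify`` the split preserves class proportions per label
    (``labels`` required); otherwise records are assigned purely at random,
    which is the default.
    """
    n = len(records)
    if n < 5:
        raise ModelError(f"need at least 5 records to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(n * spec.train_fraction))
    if spec.stratify:
        if labels is None:
            raise ModelError("stratified split requires labels")
        labels = np.asarray(labels)
        train_idx: list[int] = []
        for cls in np.unique(labels):
            idx = np.nonzero(labels == cls)[0]
            perm = rng.permutation(idx)
            k = int(round(len(idx) * spec.train_fraction))
            train_idx.extend(perm[:k].tolist())
        train_set = set(train_idx)
    else:
        perm = rng.permutation(n)
        train_set = set(perm[:n_train].tolist())
    train = [records[i] for i in range(n) if i in train_set]
    test = [records[i] for i in range(n) if i not in train_set]
    return train, test


# ---------------------------------------------------------------------------
# Batch-normalised sigmoid MLP (numpy, RMSProp)
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _BatchNorm:
    """Standard batch normalisation with learnable scale/shift and running
    statistics for inference."""

    def __init__(self, dim: int, momentum: float, eps: float = 1e-3):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xhat, inv_std = self._cache
        n = dy.shape[0]
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        dx = (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx, dgamma, dbeta

    def params(self):
        return [("gamma", self), ("beta", self)]


class _MlpNet:
    """6 → h1 → h2 → 1, sigmoid everywhere, BN after each hidden activation
    and before the output node's input."""

    def __init__(self, n_in: int, config: MlpConfig):
        rng = np.random.default_rng(config.seed)
        h1, h2 = config.hidden
        def init(fan_in, fan_out):
            return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out))
        self.W1, self.b1 = init(n_in, h1), np.zeros(h1)
        self.W2, self.b2 = init(h1, h2), np.zeros(h2)
        self.W3, self.b3 = init(h2, 1), np.zeros(1)
        self.bn1 = _BatchNorm(h1, config.bn_momentum)
        self.bn2 = _BatchNorm(h2, config.bn_momentum)
        self.config = config
        self._rms: dict[str, np.ndarray] = {}

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        self._X = X
        self._a1 = _sigmoid(X @ self.W1 + self.b1)
        self._n1 = self.bn1.forward(self._a1, training)
        self._a2 = _sigmoid(self._n1 @ self.W2 + self.b2)
        self._n2 = self.bn2.forward(self._a2, training)
        self._p = _sigmoid(self._n2 @ self.W3 + self.b3)
        return self._p[:, 0]

    # -- backward (BCE loss gradient) --------------------------------------
    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        n = y.shape[0]
        # d(BCE)/d(logit) for a sigmoid output
        dz3 = (self._p - y[:, None]) / n
        grads = {
            "W3": self._n2.T @ dz3,
            "b3": dz3.sum(axis=0),
        }
        dn2 = dz3 @ self.W3.T
        da2, grads["bn2.gamma"], grads["bn2.beta"] = self.bn2.backward(dn2)
        dz2 = da2 * self._a2 * (1 - self._a2)
        grads["W2"] = self._n1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dn1 = dz2 @ self.W2.T
        da1, grads["bn1.gamma"], grads["bn1.beta"] = self.bn1.backward(dn1)
        dz1 = da1 * self._a1 * (1 - self._a1)
        grads["W1"] = self._X.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def _param_ref(self, key: str):
        if "." in key:
            bn_name, attr = key.split(".")
            return getattr(self, bn_name), attr
        return self, key

    def apply_gradients(self, grads: dict[str, np.ndarray]):
        cfg = self.config
        for key, g in grads.items():
            cache = self._rms.setdefault(key, np.zeros_like(g))
            cache *= cfg.rmsprop_rho
            cache += (1 - cfg.rmsprop_rho) * g * g
            obj, attr = self._param_ref(key)
            setattr(obj, attr,
                    getattr(obj, attr) - cfg.learning_rate * g / (np.sqrt(cache) + cfg.rmsprop_eps))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# Trained-classifier container
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """A fitted model plus the preprocessing it was trained with."""

    kind: str                      # "lda" | "qda" | "mlp"
    estimator: object
    scaler: Scaler | None = None
    threshold_uM: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray, scaled: bool = False) -> np.ndarray:
        """Activity probability per row.  Raw features are standardised with
        the attached scaler unless ``scaled=True``."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.metadata.get("n_features", N_FEATURES):
            raise ModelError(
                f"expected {self.metadata.get('n_features', N_FEATURES)} "
                f"features, got {X.shape[1]}"
            )
        if not scaled:
            if self.scaler is None:
                raise ModelError("model has no attached scaler for raw features")
            X = self.scaler.transform(X)
        if self.kind == "mlp":
            return self.estimator.predict_proba(X)
        return self.estimator.predict_proba(X)[:, 1]


def _check_classes(y: np.ndarray):
    classes = np.unique(y)
    if classes.size < 2:
        raise ModelError(
            f"both classes must be present; got only class(es) {classes.tolist()}"
        )


def train_discriminant(kind: str, features: np.ndarray, labels: Sequence[int],
                       scaler: Scaler | None = None,
                       threshold_uM: float | None = None,
                       reg: float = 1e-6) -> TrainedClassifier:
    """Fit LDA (pooled covariance) or QDA (per-class covariances).

    Priors are the empirical class frequencies; probabilities come from the
    Gaussian posterior.  A small covariance regulariser guards against
    singular 6-D covariances at small n.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    kind = kind.lower()
    if kind == "lda":
        est = LinearDiscriminantAnalysis()
    elif kind == "qda":
        est = QuadraticDiscriminantAnalysis(reg_param=reg)
    else:
        raise ModelError(f"unknown discriminant kind {kind!r}")
    est.fit(X, y)
    return TrainedClassifier(
        kind=kind, estimator=est, scaler=scaler, threshold_uM=threshold_uM,
        metadata={"n_features": X.shape[1], "n_train": X.shape[0], "reg": reg},
    )


def train_mlp(features: np.ndarray, labels: Sequence[int],
              config: MlpConfig = MlpConfig(),
              scaler: Scaler | None = None,
              threshold_uM: float | None = None) -> TrainedClassifier:
    """Train the fixed-architecture perceptron; seeded and reproducible.

    The per-epoch loss trace is kept in the metadata (sub-sampled) and the
    run aborts with the offending epoch if the loss goes non-finite.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    _check_classes(y.astype(int))
    net = _MlpNet(X.shape[1], config)
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            p = net.forward(X[idx], training=True)
            loss = _bce(p, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch, loss)
            losses.append(loss)
            net.apply_gradients(net.backward(y[idx]))
        trace.append(float(np.mean(losses)))
    logger.info("mlp training: %d epochs, final loss %.5f", config.epochs,
                trace[-1] if trace else float("nan"))
    return TrainedClassifier(
        kind="mlp", estimator=net, scaler=scaler, threshold_uM=threshold_uM,
        metadata={
            "n_features": X.shape[1], "n_train": n,
            "config": asdict(config),
            "normalization": "batch_norm",  # in place of batch renormalisation
            "loss_trace": trace[:: max(1, len(trace) // 50)],
            "final_loss": trace[-1] if trace else None,
        },
    )


def fit_classifier(kind: str, raw_features: np.ndarray, labels: Sequence[int],
                   threshold_uM: float | None = None,
                   mlp_config: MlpConfig | None = None) -> TrainedClassifier:
    """Convenience: fit scaler on the training rows, scale, train, attach."""
    scaler = fit_scaler(raw_features)
    X = scaler.transform(raw_features)
    if kind.lower() == "mlp":
        return train_mlp(X, labels, mlp_config or MlpConfig(),
                         scaler=scaler, threshold_uM=threshold_uM)
    return train_discriminant(kind, X, labels, scaler=scaler,
                              threshold_uM=threshold_uM)


def predict_proba(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`TrainedClassifier.predict_proba`."""
    return model.predict_proba(features)


def cross_validate(kind: str, raw_features: np.ndarray, labels: Sequence[int],
                   k: int = 5, seed: int = 0,
                   mlp_config: MlpConfig | None = None,
                   stratified: bool = True) -> dict:
    """k-fold CV with the scaler re-fitted inside each fold (no leakage).

    Stratified by default so every fold keeps both classes at small n.
    Returns per-fold AUCs with their mean and standard deviation.
    """
    from .evaluation import roc_auc  # local import to avoid a cycle

    X = np.atleast_2d(np.asarray(raw_features, dtype=float))
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    if k < 2:
        raise ModelError("k must be >= 2")
    splitter = (StratifiedKFold(k, shuffle=True, random_state=seed)
                if stratified else KFold(k, shuffle=True, random_state=seed))
    fold_aucs = []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ModelError(
                f"fold {fold} lost a class; use stratified CV or another seed"
            )
        model = fit_classifier(kind, X[tr], y[tr],
                               mlp_config=mlp_config)
        probs = model.predict_proba(X[te])
        fold_aucs.append(roc_auc(probs, y[te], higher_is_active=True).auc)
    arr = np.asarray(fold_aucs)
    return {"fold_aucs": fold_aucs, "mean": float(arr.mean()),
            "std": float(arr.std()), "k": k, "seed": seed, "kind": kind}


# ---------------------------------------------------------------------------
# Serialization: one artifact file + JSON metadata sidecar
# ---------------------------------------------------------------------------


def save_model(model: TrainedClassifier, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "kind": model.kind,
        "threshold_uM": model.threshold_uM,
        "scaler": model.scaler.to_dict() if model.scaler else None,
        "scaler_hash": model.scaler.metadata_hash() if model.scaler else None,
        "metadata": {k: v for k, v in model.metadata.items() if k != "loss_trace"},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )
    return path


def load_model(path: str | Path) -> TrainedClassifier:
    return joblib.load(Path(path))
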