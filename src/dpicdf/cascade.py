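"""Cascade deep-forest classifier.

A layered ensemble in the gcForest tradition: each layer holds four
heterogeneous tree learners (one gradient-boosted ensemble, one random
forest, two extremely-randomized-tree forests by default). A layer's class
probabilities — estimated out-of-fold so no sample is scored by a model
that saw it — are concatenated with the *original* feature vector to form
the next layer's input ("augmented attributes", d + n_estimators * 2
columns). Layers are added while the internal validation accuracy
improves; the best layer is used at inference, where the final output is
the mean of its estimators' probability vectors.

Forest learners sample sqrt(d) candidate features at each node split; the
gradient-boosted learner uses per-tree column subsampling at the same rate.
All randomness derives deterministically from one master seed, so a full
fit/predict run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "CascadeConfig",
    "CascadeModel",
    "CascadeClassifier",
    "layer_seeds",
    "make_estimator",
    "fit_layer",
    "fit_cascade",
    "predict_proba",
    "predict",
    "save_model",
    "load_model",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class CascadeConfig:
    """Architecture and growth parameters of the cascade.

    ``estimators_per_layer`` names the learner family of each slot:
    ``"xgb"`` (gradient-boosted trees), ``"rf"`` (random forest), ``"erf"``
    (extra-trees). ``patience`` is the number of consecutive layers without
    a validation improvement tolerated before growth stops.
    """

    estimators_per_layer: tuple = ("xgb", "rf", "erf", "erf")
    trees_per_estimator: int = 100
    internal_cv_folds: int = 3
    max_layers: int = 20
    patience: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.estimators_per_layer) < 1:
            raise ValueError("need at least one estimator per layer")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if self.internal_cv_folds < 2:
            raise ValueError(
                "internal_cv_folds must be >= 2 (no out-of-fold estimate otherwise)"
            )

    @property
    def n_estimators(self) -> int:
        return len(self.estimators_per_layer)


def layer_seeds(master_seed: int, layer_index: int, n: int) -> np.ndarray:
    """Deterministic sub-seeds (< 2**31) for one layer's estimators/folds."""
    ss = np.random.SeedSequence([int(master_seed), int(layer_index)])
    return ss.generate_state(n, dtype=np.uint64) % _MAX_SEED


def make_estimator(kind: str, d: int, seed: int, cfg: CascadeConfig):
    """Instantiate one base learner with sqrt(d) feature subsampling."""
    seed = int(seed)
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.trees_per_estimator, max_features="sqrt",
            random_state=seed, n_jobs=1,
        )
    if kind == "erf":
        return ExtraTreesClassifier(
            n_estimators=cfg.trees_per_estimator, max_features="sqrt",
            random_state=seed, n_jobs=1,
        )
    if kind == "xgb":
        return XGBClassifier(
            n_estimators=cfg.trees_per_estimator,
            colsample_bytree=float(np.sqrt(d) / d),
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", verbosity=0,
        )
    raise ValueError(f"unknown estimator kind {kind!r}")


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if classes.size != 2 or not set(classes) <= {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    return X, y


def fit_layer(X: np.ndarray, y: np.ndarray, cfg: CascadeConfig, layer_index: int):
    """Fit one layer: full-data estimators plus out-of-fold probabilities.

    Returns ``(estimators, oof)`` where ``oof`` is n x (n_estimators * 2):
    each sample's class probabilities come from clones not trained on it.
    """
    X, y = _check_xy(X, y)
    n = X.shape[0]
    seeds = layer_seeds(cfg.seed, layer_index, cfg.n_estimators + 1)
    skf = StratifiedKFold(
        n_splits=cfg.internal_cv_folds, shuffle=True, random_state=int(seeds[-1])
    )
    folds = list(skf.split(X, y))

    estimators, oof_parts = [], []
    for k, kind in enumerate(cfg.estimators_per_layer):
        oof = np.zeros((n, 2))
        for train_idx, test_idx in folds:
            clone = make_estimator(kind, X.shape[1], seeds[k], cfg)
            clone.fit(X[train_idx], y[train_idx])
            oof[test_idx] = clone.predict_proba(X[test_idx])
        oof_parts.append(oof)
        full = make_estimator(kind, X.shape[1], seeds[k], cfg)
        full.fit(X, y)
        estimators.append(full)
    return estimators, np.hstack(oof_parts)


def _mean_proba(P: np.ndarray, n_estimators: int) -> np.ndarray:
    return P.reshape(P.shape[0], n_estimators, 2).mean(axis=1)


@dataclass
class CascadeModel:
    """A fitted cascade: ordered layers plus growth metadata."""

    config: CascadeConfig
    layers: list = field(default_factory=list)
    layer_scores: list = field(default_factory=list)
    best_layer: int = 0  # 0-based index of the layer used at inference
    d_in: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def fit_cascade(X: np.ndarray, y: np.ndarray, cfg: CascadeConfig | None = None) -> CascadeModel:
    """Grow the cascade until validation accuracy stops improving.

    Layer 1 consumes X; layer t >= 2 consumes X concatenated with layer
    t-1's out-of-fold probabilities. The validation score of a layer is the
    accuracy of its averaged out-of-fold probabilities; growth stops after
    ``patience`` consecutive layers without a new best, or at
    ``max_layers``. Layers beyond the best are discarded.
    """
    cfg = cfg or CascadeConfig()
    X, y = _check_xy(X, y)
    if X.shape[0] < 2 * cfg.internal_cv_folds:
        raise ValueError("too few samples for the internal cross-fitting")

    model = CascadeModel(config=cfg, d_in=X.shape[1])
    X_t = X
    best_score, stale = -np.inf, 0
    for t in range(cfg.max_layers):
        estimators, oof = fit_layer(X_t, y, cfg, layer_index=t)
        score = float((np.argmax(_mean_proba(oof, cfg.n_estimators), axis=1) == y).mean())
        model.layers.append(estimators)
        model.layer_scores.append(score)
        if score > best_score:
            best_score, stale = score, 0
            model.best_layer = t
        else:
            stale += 1
            if stale >= cfg.patience:
                break
        X_t = np.hstack([X, oof])
    del model.layers[model.best_layer + 1 :]
    del model.layer_scores[model.best_layer + 1 :]
    return model


def predict_proba(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Propagate through layers 1..best and average the last layer's outputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.d_in:
        raise ValueError(f"expected {model.d_in} features, got {X.shape}")
    k = model.config.n_estimators
    X_t = X
    for t, layer in enumerate(model.layers):
        P = np.hstack([est.predict_proba(X_t) for est in layer])
        if t < model.n_layers - 1:
            X_t = np.hstack([X, P])
    return _mean_proba(P, k)


def predict(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Class labels; an exact 0.5/0.5 tie resolves to the negative class."""
    proba = predict_proba(model, X)
    return (proba[:, 1] > proba[:, 0]).astype(int)


class CascadeClassifier:
    """Thin sklearn-style wrapper around the functional cascade API."""

    def __init__(self, config: CascadeConfig | None = None, seed: int | None = None):
        cfg = config or CascadeConfig()
        if seed is not None:
            cfg = replace(cfg, seed=int(seed))
        self.config = cfg
        self.model_: CascadeModel | None = None

    def fit(self, X, y):
        self.model_ = fit_cascade(X, y, self.config)
        return self

    def predict_proba(self, X):
        return predict_proba(self.model_, X)

    def predict(self, X):
        return predict(self.model_, X)


def save_model(model: CascadeModel, path) -> None:
    """Serialize a fitted cascade (config + estimators + metadata)."""
    joblib.dump(model, path)


def load_model(path) -> CascadeModel:
    model = joblib.load(path)
    if not isinstance(model, CascadeModel):
        raise TypeError(f"{path} does not contain a CascadeModel")
    return model
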