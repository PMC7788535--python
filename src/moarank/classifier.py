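"""Binary MLP classifier scoring signatures for one mechanism of action.

The model is a feed-forward network — z-score features in, hidden ReLU
layers (default 978/512/256 nodes) with dropout 0.1, a single sigmoid
output — trained by mini-batch Adam on weighted cross-entropy with an L1
weight penalty for a fixed number of optimizer steps (default 2000).  It is
implemented in NumPy as an sklearn-compatible estimator
(:class:`SignatureMLPClassifier`) so it composes with sklearn pipelines and
model selection; the domain-level ``train`` / ``score`` / ``cross_validate``
functions are thin wrappers over it.

Evaluation is drug-level K-fold cross-validation: for each fold the model
is trained on the other K-1 parts and scores the held-out signatures;
per-fold AUROC values are averaged and a model with mean AUROC >= 0.6
counts as well trained.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import metrics
from .io import SignatureMatrix, ValidationError
from .trainset import FoldPlan, TrainingSet

__all__ = [
    "ModelConfig",
    "SignatureMLPClassifier",
    "TrainedModel",
    "CVReport",
    "train",
    "score",
    "cross_validate",
    "save_model",
    "load_model",
]

WELL_TRAINED_AUROC = 0.6


@dataclass
class ModelConfig:
    """Hyperparameters of the MOA classifier.

    Defaults follow the published architecture: 3 hidden layers of
    978/512/256 nodes, 2000 optimizer steps, ReLU, dropout 0.1, L1
    regularization.  Optimizer (Adam), learning rate, L1 strength, batch
    size and class weighting are unstated there and exposed here.
    """

    hidden_layers: tuple[int, ...] = (978, 512, 256)
    iterations: int = 2000
    dropout_rate: float = 0.1
    l1_lambda: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 128
    class_weighting: str = "balanced"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if not self.hidden_layers or any(h < 1 for h in self.hidden_layers):
            raise ValidationError("hidden_layers must be non-empty positive counts")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        for name in ("iterations", "l1_lambda", "learning_rate", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.class_weighting not in ("balanced", "none"):
            raise ValidationError("class_weighting must be 'balanced' or 'none'")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SignatureMLPClassifier(BaseEstimator, ClassifierMixin):
    """Feed-forward binary classifier with ReLU, dropout and L1 penalty.

    Deterministic under ``seed``: identical inputs and seed give bitwise
    identical weights and probabilities.  ``predict_proba`` runs with
    dropout disabled.

    Parameters mirror :class:`ModelConfig`; fitted attributes are
    ``coefs_``, ``intercepts_``, ``classes_``, ``n_features_in_`` and
    ``loss_curve_``.
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (978, 512, 256),
        iterations: int = 2000,
        dropout_rate: float = 0.1,
        l1_lambda: float = 1e-4,
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        class_weighting: str = "balanced",
        seed: int = 0,
    ) -> None:
        self.hidden_layers = hidden_layers
        self.iterations = iterations
        self.dropout_rate = dropout_rate
        self.l1_lambda = l1_lambda
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.class_weighting = class_weighting
        self.seed = seed

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "SignatureMLPClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D with one row per label")
        if not np.isfinite(X).all():
            raise ValidationError("X contains non-finite values")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValidationError("need both classes (labels 0 and 1) to train")
        ModelConfig(**self.get_params())  # validate hyperparameters

        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        sizes = [d, *self.hidden_layers, 1]
        # He initialization for ReLU layers
        W = [
            rng.standard_normal((sizes[i], sizes[i + 1])) * np.sqrt(2.0 / sizes[i])
            for i in range(len(sizes) - 1)
        ]
        b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

        if self.class_weighting == "balanced":
            n_pos = y.sum()
            w_sample = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
        else:
            w_sample = np.ones(n)

        batch = min(self.batch_size, n)
        lr, lam, p_drop = self.learning_rate, self.l1_lambda, self.dropout_rate
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        loss_curve = []

        for step in range(1, self.iterations + 1):
            idx = rng.choice(n, size=batch, replace=False) if batch < n else np.arange(n)
            a = X[idx]
            yb, wb = y[idx], w_sample[idx]
            acts = [a]
            masks = []
            for li in range(len(W) - 1):
                a = np.maximum(a @ W[li] + b[li], 0.0)
                if p_drop > 0:
                    mask = (rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(a)
            z = (a @ W[-1] + b[-1]).ravel()
            p = _sigmoid(z)
            p_c = np.clip(p, 1e-12, 1 - 1e-12)
            data_loss = -np.mean(wb * (yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c)))
            loss = data_loss + lam * sum(np.abs(w).sum() for w in W)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at step {step}")
            loss_curve.append(float(loss))

            # backward pass
            delta = (wb * (p - yb) / len(yb))[:, None]  # dL/dz_out
            grads_W, grads_b = [None] * len(W), [None] * len(W)
            for li in range(len(W) - 1, -1, -1):
                grads_W[li] = acts[li].T @ delta + lam * np.sign(W[li])
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ W[li].T
                    if masks[li - 1] is not None:
                        delta = delta * masks[li - 1]
                    delta = delta * (acts[li] > 0)

            # Adam update
            t = step
            for li in range(len(W)):
                mW[li] = beta1 * mW[li] + (1 - beta1) * grads_W[li]
                vW[li] = beta2 * vW[li] + (1 - beta2) * grads_W[li] ** 2
                mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                mhW = mW[li] / (1 - beta1**t)
                vhW = vW[li] / (1 - beta2**t)
                mhb = mb[li] / (1 - beta1**t)
                vhb = vb[li] / (1 - beta2**t)
                W[li] -= lr * mhW / (np.sqrt(vhW) + eps)
                b[li] -= lr * mhb / (np.sqrt(vhb) + eps)

        self.coefs_ = W
        self.intercepts_ = b
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        self.loss_curve_ = loss_curve
        return self

    # -- inference ----------------------------------------------------------

    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for li in range(len(self.coefs_) - 1):
            a = np.maximum(a @ self.coefs_[li] + self.intercepts_[li], 0.0)
        return _sigmoid((a @ self.coefs_[-1] + self.intercepts_[-1]).ravel())

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        p = self._forward(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Domain wrappers


@dataclass
class TrainedModel:
    """A fitted classifier bound to its feature gene order."""

    config: ModelConfig
    feature_gene_ids: list[str]
    estimator: SignatureMLPClassifier
    training_fingerprint: str
    moa_name: str = "moa"


@dataclass
class CVReport:
    """Drug-level cross-validation summary.

    ``fold_aurocs`` has one entry per fold; a fold whose held-out labels are
    single-class has an undefined AUROC, recorded as NaN and excluded from
    the mean.  ``well_trained`` is mean AUROC >= 0.6.
    """

    fold_aurocs: list[float]
    mean_auroc: float
    ap_score: float
    well_trained: bool
    fold_plan: FoldPlan

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, "auroc": a} for i, a in enumerate(self.fold_aurocs)]
        rows.append({"fold": "mean", "auroc": self.mean_auroc})
        rows.append({"fold": "ap_score", "auroc": self.ap_score})
        rows.append({"fold": "well_trained", "auroc": self.well_trained})
        return pd.DataFrame(rows)


def _fingerprint(X: np.ndarray, y: np.ndarray, config: ModelConfig) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(json.dumps(asdict(config), sort_keys=True, default=list).encode())
    return h.hexdigest()[:16]


def _design(training_set: TrainingSet, matrix: SignatureMatrix):
    """(X, y) with rows in training-set entry order, columns in feature order."""
    sub = matrix.subset_genes(training_set.feature_gene_ids)
    sub = sub.subset_signatures(training_set.sig_ids)
    return sub.values.T, training_set.labels


def train(
    training_set: TrainingSet, matrix: SignatureMatrix, config: ModelConfig | None = None
) -> TrainedModel:
    """Fit the MLP on all signatures of a training set."""
    config = config or ModelConfig()
    X, y = _design(training_set, matrix)
    est = SignatureMLPClassifier(**asdict(config)).fit(X, y)
    return TrainedModel(
        config=config,
        feature_gene_ids=list(training_set.feature_gene_ids),
        estimator=est,
        training_fingerprint=_fingerprint(X, y, config),
        moa_name=training_set.moa_name,
    )


def score(model: TrainedModel, matrix: SignatureMatrix) -> pd.Series:
    """Positive-class probability for every signature column.

    The matrix must contain all of the model's feature genes (extra genes
    are dropped after alignment; missing genes raise an error listing them);
    dropout is disabled.
    """
    aligned = matrix.subset_genes(model.feature_gene_ids)
    probs = model.estimator.predict_proba(aligned.values.T)[:, 1]
    return pd.Series(probs, index=aligned.sig_ids, name="probability")


def cross_validate(
    training_set: TrainingSet,
    matrix: SignatureMatrix,
    config: ModelConfig | None = None,
    fold_plan: FoldPlan | None = None,
) -> CVReport:
    """Drug-level K-fold cross-validation of one MOA model."""
    from .trainset import plan_folds

    config = config or ModelConfig()
    if fold_plan is None:
        fold_plan = plan_folds(training_set, seed=config.seed)
    X, y = _design(training_set, matrix)
    fold_aurocs: list[float] = []
    pooled_scores = np.full(len(y), np.nan)
    for fold in range(fold_plan.K):
        test = fold_plan.test_mask(training_set, fold)
        if test.all() or not test.any():
            raise ValidationError(f"fold {fold} leaves no train or no test signatures")
        est = SignatureMLPClassifier(**asdict(config)).fit(X[~test], y[~test])
        p = est.predict_proba(X[test])[:, 1]
        pooled_scores[test] = p
        if len(np.unique(y[test])) < 2:
            warnings.warn(f"fold {fold}: single-class test labels; AUROC undefined")
            fold_aurocs.append(float("nan"))
        else:
            fold_aurocs.append(metrics.auroc(p, y[test]))
    defined = [a for a in fold_aurocs if np.isfinite(a)]
    if not defined:
        raise ValidationError("AUROC undefined in every fold")
    mean_auroc = float(np.mean(defined))
    scored = np.isfinite(pooled_scores)
    ap = metrics.average_precision(pooled_scores[scored], y[scored])
    return CVReport(
        fold_aurocs=fold_aurocs,
        mean_auroc=mean_auroc,
        ap_score=ap,
        well_trained=mean_auroc >= WELL_TRAINED_AUROC,
        fold_plan=fold_plan,
    )


# ---------------------------------------------------------------------------
# Serialization: one .npz archive holding config, gene list and weights.


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "config": json.dumps(asdict(model.config), default=list),
        "genes": json.dumps(model.feature_gene_ids),
        "fingerprint": model.training_fingerprint,
        "moa_name": model.moa_name,
        "n_layers": len(model.estimator.coefs_),
    }
    arrays = {}
    for i, (w, bias) in enumerate(zip(model.estimator.coefs_, model.estimator.intercepts_)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = bias
    np.savez_compressed(path, meta=json.dumps(payload), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        payload = json.loads(str(data["meta"]))
        config = ModelConfig(**json.loads(payload["config"]))
        genes = json.loads(payload["genes"])
        nl = int(payload["n_layers"])
        est = SignatureMLPClassifier(**asdict(config))
        est.coefs_ = [data[f"W{i}"] for i in range(nl)]
        est.intercepts_ = [data[f"b{i}"] for i in range(nl)]
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = est.coefs_[0].shape[0]
        est.loss_curve_ = []
    return TrainedModel(
        config=config,
        feature_gene_ids=genes,
        estimator=est,
        training_fingerprint=payload["fingerprint"],
        moa_name=payload["moa_name"],
    )
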