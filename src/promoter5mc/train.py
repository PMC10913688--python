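"""Class-weighted training and the five-fold cross-validation protocol.

Training minimises a class-weighted negative log-likelihood with Adam. The
positive-class weight defaults to the negative:positive count ratio of the
training data (7.6 on the reference benchmark composition), which boosts the
minority class during backpropagation instead of resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import autodiff as ad
from .autodiff import Tensor
from .metrics import MetricsReport, mean_report
from .nn import ModelConfig, Promoter5mCNet, build_model

__all__ = [
    "ClassWeights", "TrainSpec", "compute_class_weights", "weighted_loss",
    "Adam", "fit", "run_cv", "cv_folds",
]

_LOG_EPS = 1e-12  # clamp for log-probabilities


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss multipliers; both strictly positive."""

    w_pos: float
    w_neg: float = 1.0

    def __post_init__(self):
        if self.w_pos <= 0 or self.w_neg <= 0:
            raise ValueError("class weights must be positive")

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(labels) == 1, self.w_pos, self.w_neg)


def compute_class_weights(n_pos: int, n_neg: int) -> ClassWeights:
    """Inverse-prevalence weighting: w_pos = n_neg / n_pos, w_neg = 1."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be non-empty to compute class weights")
    return ClassWeights(w_pos=n_neg / n_pos, w_neg=1.0)


def weighted_loss(probs, labels, weights: ClassWeights | None = None) -> Tensor:
    """Mean over samples of weight(label) * -log P(true class).

    ``probs`` is an (N, 2) tensor/array of class probabilities; probabilities
    are clamped at 1e-12 before the logarithm.
    """
    probs = Tensor._coerce(probs)
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels disagree in length")
    n = labels.shape[0]
    p_true = probs[np.arange(n), labels]
    nll = -(p_true.clamp_min(_LOG_EPS).log())
    if weights is not None:
        nll = nll * Tensor(weights.per_sample(labels).astype(probs.data.dtype))
    return nll.mean()


@dataclass(frozen=True)
class TrainSpec:
    """Optimisation hyperparameters (none are dictated by the task)."""

    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def small(cls, **overrides) -> "TrainSpec":
        """A short schedule sized for CPU-scale experiments."""
        base = dict(epochs=5, batch_size=128)
        base.update(overrides)
        return cls(**base)

    def replace(self, **kw) -> "TrainSpec":
        return replace(self, **kw)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _epoch_loss(model: Promoter5mCNet, x: np.ndarray, y: np.ndarray,
                weights: ClassWeights | None, batch_size: int) -> float:
    was_training = model.training
    model.eval()
    try:
        total, n = 0.0, 0
        with ad.no_grad():
            for lo in range(0, len(x), batch_size):
                xb, yb = x[lo:lo + batch_size], y[lo:lo + batch_size]
                total += float(weighted_loss(model(xb), yb, weights).data) * len(yb)
                n += len(yb)
        return total / n
    finally:
        model.train(was_training)


def fit(model: Promoter5mCNet, x: np.ndarray, y: np.ndarray,
        spec: TrainSpec | None = None, weights: ClassWeights | None = None,
        x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
        verbose: bool = False) -> dict[str, list[float]]:
    """Train ``model`` in place; returns the per-epoch loss history.

    Early stopping (restore-best) monitors validation loss when validation
    data is given, with the spec's patience. Deterministic for a fixed spec
    seed on one platform.
    """
    spec = spec or TrainSpec()
    x = np.asarray(x, dtype=model.config.dtype)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(spec.seed)
    opt = Adam(model.parameters(), lr=spec.learning_rate)
    history: dict[str, list[float]] = {"train_loss": []}
    if x_val is not None:
        history["val_loss"] = []
    best_val, best_state, strikes = np.inf, None, 0
    model.train()
    for epoch in range(spec.epochs):
        order = rng.permutation(len(y))
        running, seen = 0.0, 0
        for lo in range(0, len(order), spec.batch_size):
            idx = order[lo:lo + spec.batch_size]
            opt.zero_grad()
            probs = model(x[idx])
            loss = weighted_loss(probs, y[idx], weights)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {lo // spec.batch_size}")
            loss.backward()
            opt.step()
            running += value * len(idx)
            seen += len(idx)
        history["train_loss"].append(running / seen)
        msg = f"epoch {epoch + 1}/{spec.epochs} train_loss={history['train_loss'][-1]:.4f}"
        if x_val is not None:
            val = _epoch_loss(model, x_val, np.asarray(y_val, dtype=int), weights, spec.batch_size)
            history["val_loss"].append(val)
            msg += f" val_loss={val:.4f}"
            if val < best_val - 1e-6:
                best_val, best_state, strikes = val, model.state_dict(), 0
            else:
                strikes += 1
                if strikes >= spec.patience:
                    if verbose:
                        print(msg + "  (early stop)")
                    break
        if verbose:
            print(msg)
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def cv_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold indices: a partition of samples into k validation
    folds with per-fold class ratios matching the whole within rounding."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"both classes need >= {k} members for {k}-fold CV")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(folds.split(np.zeros((len(y), 1)), y))


def run_cv(x: np.ndarray, y: np.ndarray, k: int = 5,
           config: ModelConfig | None = None, spec: TrainSpec | None = None,
           threshold: float = 0.5, use_class_weights: bool = True,
           verbose: bool = False) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation.

    Each fold trains a fresh model on the other k-1 folds (class weights
    recomputed from that fold's training portion) and is evaluated on the
    held-out fold; the summary report is the arithmetic mean of the fold
    metrics.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    config = config or ModelConfig()
    spec = spec or TrainSpec()
    reports: list[MetricsReport] = []
    for fold, (train_idx, val_idx) in enumerate(cv_folds(y, k, spec.seed)):
        model = build_model(config.replace(seed=config.seed + fold))
        y_tr = y[train_idx]
        weights = (compute_class_weights(int((y_tr == 1).sum()), int((y_tr == 0).sum()))
                   if use_class_weights else None)
        fit(model, x[train_idx], y_tr, spec, weights, verbose=False)
        scores = model.predict_scores(x[val_idx])
        report = MetricsReport.from_scores(y[val_idx], scores, threshold=threshold)
        reports.append(report)
        if verbose:
            print(f"fold {fold + 1}/{k}: {report}")
    return reports, mean_report(reports)
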