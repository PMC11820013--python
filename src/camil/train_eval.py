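"""Training loop, cross-validation and the binary metric suite.

Training follows the bag-at-a-time regime standard for MIL: Adam with an
initial learning rate of 1e-4 and weight decay 1e-5, a cosine-annealed
learning rate over the epoch budget (default 50), one bag per gradient
step, binary cross-entropy on the bag logit, and early stopping on
validation AUC (patience 10).  The parameters returned are those of the
best validation-AUC epoch.

Evaluation reports accuracy at a 0.5 threshold, ROC AUC, specificity,
recall and F1, aggregated over stratified k-fold cross-validation (default
10 folds) as mean +/- standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data_model import Bag, validate_bag
from .model import CamilConfig, CamilModel

METRIC_NAMES = ("accuracy", "auc", "specificity", "recall", "f1")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the training recipe)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 50
    early_stop_patience: int = 10
    seed: int = 0
    threshold: float = 0.5
    folds: int = 10
    val_fraction: float = 0.2  # inner stratified split used for early stopping

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from lr0 at epoch 0 down to 0 at the final epoch."""
    if total_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))


class Adam:
    """Plain Adam with decoupled-from-schedule L2 weight decay added to the gradient."""

    def __init__(self, params: Dict[str, np.ndarray], weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k] + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _labels(bags: Sequence[Bag]) -> np.ndarray:
    return np.array([b.y for b in bags], dtype=int)


def train_model(
    model: CamilModel,
    train_bags: Sequence[Bag],
    cfg: TrainConfig,
    val_bags: Optional[Sequence[Bag]] = None,
) -> Tuple[Dict[str, np.ndarray], List[Dict[str, float]]]:
    """Train in place; return (best parameters, per-epoch history).

    ``history`` rows hold epoch, learning rate, mean training loss and
    validation AUC.  Early stopping monitors validation AUC; when no
    validation set is given the final-epoch parameters are returned and
    the mean training loss is monitored for the stopping rule instead.
    """
    train_bags = [validate_bag(b) for b in train_bags]
    y_train = _labels(train_bags)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, weight_decay=cfg.weight_decay)
    history: List[Dict[str, float]] = []
    best_auc = -np.inf
    best_loss = np.inf
    best_params = model.clone_params()
    stale = 0
    for epoch in range(cfg.epochs):
        lr = cosine_lr(cfg.learning_rate, epoch, cfg.epochs)
        order = rng.permutation(len(train_bags))
        losses = []
        for idx in order:
            bag = train_bags[idx]
            loss, grads = model.loss_and_grads(bag.X, bag.y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, bag {bag.slide_id!r}: {loss}"
                )
            opt.step(grads, lr)
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        if val_bags:
            val_probs = model.predict_proba(val_bags)
            monitor = auc_score(_labels(val_bags), val_probs)
            val_loss = float(np.mean([
                _bce(p, b.y) for p, b in zip(val_probs, val_bags)
            ]))
            row = {"epoch": epoch, "lr": lr, "train_loss": mean_loss,
                   "val_auc": monitor, "val_loss": val_loss}
        else:
            monitor, val_loss = -mean_loss, mean_loss
            row = {"epoch": epoch, "lr": lr, "train_loss": mean_loss,
                   "val_auc": float("nan"), "val_loss": float("nan")}
        history.append(row)
        # patience counts epochs without AUC improvement; among equal-AUC
        # epochs the one with the lowest validation loss is kept (better
        # calibrated decision threshold)
        if monitor > best_auc + 1e-12:
            best_auc, best_loss = monitor, val_loss
            best_params = model.clone_params()
            stale = 0
        else:
            if monitor >= best_auc - 1e-12 and val_loss < best_loss:
                best_loss = val_loss
                best_params = model.clone_params()
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    model.params = {k: v.copy() for k, v in best_params.items()}
    return best_params, history


def _bce(prob: float, y: int, eps: float = 1e-12) -> float:
    prob = min(max(prob, eps), 1 - eps)
    return -(y * np.log(prob) + (1 - y) * np.log(1 - prob))


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


def binary_metrics(labels, probs, threshold: float = 0.5) -> Dict[str, float]:
    """Confusion-matrix metric suite at the given decision threshold.

    specificity = TN/(TN+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R) with the 0/0 case defined as 0.
    AUC is included when both classes are present, else NaN.
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {probs.shape} probs")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n if n else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    denom = precision + (recall if np.isfinite(recall) else 0.0)
    f1 = (2 * precision * recall / denom) if denom > 0 and np.isfinite(recall) else 0.0
    auc = auc_score(labels, probs) if len(np.unique(labels)) == 2 else float("nan")
    return {
        "accuracy": accuracy,
        "auc": auc,
        "specificity": specificity,
        "recall": recall,
        "f1": f1,
    }


def auc_score(labels, probs) -> float:
    """ROC AUC: the Mann-Whitney concordance probability, ties counted 0.5."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("auc_score requires both classes")
    return float(roc_auc_score(labels, probs))


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-fold metric rows plus mean/std aggregates."""

    per_fold: List[Dict[str, float]]
    mean: Dict[str, float] = field(default_factory=dict)
    std: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_fold and not self.mean:
            for name in METRIC_NAMES:
                vals = np.array([row[name] for row in self.per_fold], dtype=float)
                self.mean[name] = float(np.nanmean(vals))
                self.std[name] = float(np.nanstd(vals))

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = json.dumps(
            {"per_fold": self.per_fold, "mean": self.mean, "std": self.std},
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def stratified_folds(
    labels: Sequence[int], n_folds: int, seed: int
) -> List[np.ndarray]:
    """Seed-deterministic stratified fold assignment (validation indices)."""
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [val_idx for _, val_idx in skf.split(np.zeros(len(labels)), labels)]


def _inner_split(
    bags: List[Bag], cfg: TrainConfig, seed: int
) -> Tuple[List[Bag], List[Bag]]:
    y = _labels(bags)
    idx_train, idx_val = train_test_split(
        np.arange(len(bags)), test_size=cfg.val_fraction, stratify=y, random_state=seed
    )
    return [bags[i] for i in idx_train], [bags[i] for i in idx_val]


def fit_and_score(
    train_bags: List[Bag],
    test_bags: List[Bag],
    model_config: CamilConfig,
    cfg: TrainConfig,
    seed: Optional[int] = None,
) -> Tuple[CamilModel, Dict[str, float]]:
    """Train on ``train_bags`` (with an inner early-stopping split) and
    score on ``test_bags``.  The fixed-split evaluation entry point."""
    seed = cfg.seed if seed is None else seed
    inner_train, inner_val = _inner_split(list(train_bags), cfg, seed)
    model = CamilModel(CamilConfig(**{**asdict(model_config), "seed": seed}))
    run_cfg = TrainConfig(**{**asdict(cfg), "seed": seed})
    train_model(model, inner_train, run_cfg, inner_val)
    probs = model.predict_proba(test_bags)
    return model, binary_metrics(_labels(test_bags), probs, cfg.threshold)


def cross_validate(
    bags: Sequence[Bag], model_config: CamilConfig, cfg: TrainConfig
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full training recipe.

    Every bag appears in exactly one validation fold; fold assignment and
    training are deterministic given ``cfg.seed``.
    """
    bags = list(bags)
    y = _labels(bags)
    folds = stratified_folds(y, cfg.folds, cfg.seed)
    rows = []
    for k, val_idx in enumerate(folds):
        val_mask = np.zeros(len(bags), dtype=bool)
        val_mask[val_idx] = True
        train_fold = [b for b, m in zip(bags, val_mask) if not m]
        test_fold = [b for b, m in zip(bags, val_mask) if m]
        if len(np.unique(_labels(test_fold))) < 2:
            raise ValueError(
                f"fold {k} validation split is single-class; use fewer folds or more bags"
            )
        _, metrics = fit_and_score(train_fold, test_fold, model_config, cfg,
                                   seed=cfg.seed + k)
        rows.append({"fold": k, **metrics})
    return MetricsReport(per_fold=rows)
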