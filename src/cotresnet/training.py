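"""Training schedule and evaluation metrics for the slice classifiers.

The schedule follows the common medical-imaging recipe: Adam at an initial
learning rate of 3e-5 with batch size 32, cross-entropy loss, up to 100
epochs; the learning rate drops by 10× after 10 epochs without validation
improvement, training halts after 30 epochs without a training-loss
improvement, and the checkpoint with the best validation accuracy is kept.

Binary tasks report accuracy, precision and recall against a declared
positive class (by default the more-impaired class of the pair); the
three-class task reports top-1 accuracy, with macro-averaged precision and
recall available on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .architectures import ResidualNetwork
from .autodiff import Tensor, log_softmax
from .nn import Module
from .preprocessing import LABELS, SliceDataset

__all__ = [
    "TrainConfig",
    "TrainingDiverged",
    "cross_entropy_loss",
    "softmax_cross_entropy",
    "Adam",
    "PlateauScheduler",
    "EarlyStopping",
    "MetricsReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "evaluate_metrics",
    "prepare_task",
    "positive_class_for",
    "train",
    "TrainResult",
]

LOSS_EPS = 1e-12  # log(0) guard inside the loss


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 3e-5
    batch_size: int = 32
    max_epochs: int = 100
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    earlystop_patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.lr0 < 0:
            raise ValueError("lr0 must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.plateau_patience < 1 or self.earlystop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau_factor must be in (0, 1)")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray, eps: float = LOSS_EPS) -> float:
    """Mean cross-entropy of per-sample class distributions.

    ``probs`` rows must sum to 1 (±1e-6); ``labels`` are integer class
    indices.  Zero probability at the true class is clamped by ``eps``
    instead of producing an infinite loss.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2:
        raise ValueError("probs must be (n_samples, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("labels out of range")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p_true, eps, None)).mean())


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy straight from logits."""
    logp = log_softmax(logits, axis=1)
    n = logits.shape[0]
    return -logp[np.arange(n), np.asarray(labels)].mean()


# ---------------------------------------------------------------------------
# optimizer and schedule
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard defaults (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class PlateauScheduler:
    """Reduce the learning rate ×factor after `patience` epochs without
    validation-accuracy improvement; improvements reset the counter."""

    def __init__(self, lr0: float, patience: int = 10, factor: float = 0.1):
        self.lr = float(lr0)
        self.patience = patience
        self.factor = factor
        self.best = -np.inf
        self.bad_epochs = 0
        self.n_triggers = 0

    def step(self, val_accuracy: float) -> float:
        if val_accuracy > self.best:
            self.best = val_accuracy
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.n_triggers += 1
                self.bad_epochs = 0
        return self.lr


class EarlyStopping:
    """Stop when the training loss has not improved for `patience` epochs."""

    def __init__(self, patience: int = 30):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, train_loss: float) -> bool:
        if train_loss < self.best:
            self.best = train_loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """K×K count table, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Top-1 accuracy plus, for binary tasks, precision and recall.

    ``undefined`` flags metrics whose denominator was empty (reported as 0).
    """

    accuracy: float
    confusion: np.ndarray
    positive_class: str | None = None
    precision: float | None = None
    recall: float | None = None
    undefined: tuple[str, ...] = ()
    n: int = 0

    def as_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "n": self.n}
        if self.precision is not None:
            out.update(
                positive_class=self.positive_class,
                precision=self.precision,
                recall=self.recall,
            )
        if self.undefined:
            out["undefined"] = list(self.undefined)
        out["confusion"] = self.confusion.tolist()
        return out


def metrics_from_confusion(
    cm: np.ndarray, positive_index: int | None = None, positive_class: str | None = None
) -> MetricsReport:
    """Accuracy = (TP+TN)/total; precision = TP/(TP+FP); recall = TP/(TP+FN)."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm)) / total
    if cm.shape != (2, 2) or positive_index is None:
        return MetricsReport(accuracy=accuracy, confusion=cm, n=total)
    p = positive_index
    tp = int(cm[p, p])
    fp = int(cm[1 - p, p])
    fn = int(cm[p, 1 - p])
    undefined = []
    if tp + fp == 0:
        precision = 0.0
        undefined.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = tp / (tp + fn)
    return MetricsReport(
        accuracy=accuracy,
        confusion=cm,
        positive_class=positive_class,
        precision=float(precision),
        recall=float(recall),
        undefined=tuple(undefined),
        n=total,
    )


def macro_precision_recall(cm: np.ndarray) -> tuple[float, float]:
    """Unweighted one-vs-rest averages for multi-class reports."""
    cm = np.asarray(cm, dtype=float)
    tp = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(cm.sum(axis=0) > 0, tp / cm.sum(axis=0), 0.0)
        rec = np.where(cm.sum(axis=1) > 0, tp / cm.sum(axis=1), 0.0)
    return float(prec.mean()), float(rec.mean())


def positive_class_for(classes: Sequence[str]) -> str:
    """The more-impaired class of a binary task (AD > MCI > HC severity)."""
    severity = {lab: i for i, lab in enumerate(reversed(LABELS))}
    return max(classes, key=lambda c: severity[c])


# ---------------------------------------------------------------------------
# task preparation
# ---------------------------------------------------------------------------

def parse_task(task: str) -> list[str]:
    classes = task.split(":")
    if not (2 <= len(classes) <= 3) or len(set(classes)) != len(classes):
        raise ValueError(f"task must name 2 or 3 distinct classes, got {task!r}")
    for c in classes:
        if c not in LABELS:
            raise ValueError(f"unknown class {c!r}; valid classes: {LABELS}")
    return classes


def prepare_task(
    ds: SliceDataset,
    task: str,
    split: str | None = None,
    image_hw: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Select a task's slices and return (X, y, classes).

    X is (N, 1, H, W) float32 scaled to [0, 1]; y holds integer labels in the
    order the task names the classes.  ``image_hw`` bilinearly resizes the
    slices (e.g. 128 -> 224 for the canonical network input).
    """
    classes = parse_task(task)
    sub = ds if split is None else ds.partition(split)
    mask = np.isin(sub.labels, classes)
    sub = sub.subset(mask)
    if len(sub) == 0:
        raise ValueError(f"no slices for task {task!r}" + (f" in split {split!r}" if split else ""))
    images = sub.images
    if image_hw is not None and tuple(images.shape[1:]) != tuple(image_hw):
        images = np.stack(
            [
                _sk_resize(im, image_hw, order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
                for im in images
            ]
        )
    x = (images[:, None, :, :] / 255.0).astype(np.float32)
    index = {c: i for i, c in enumerate(classes)}
    y = np.array([index[lab] for lab in sub.labels], dtype=np.int64)
    return x, y, classes


def _predict_batched(model: Module, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    preds = []
    was_training = model.training
    model.eval()
    try:
        for i in range(0, len(x), batch_size):
            logits = model(Tensor(x[i : i + batch_size]))
            preds.append(logits.data.argmax(axis=1))
    finally:
        if was_training:
            model.train()
    return np.concatenate(preds)


def evaluate_metrics(
    model: Module,
    x: np.ndarray,
    y: np.ndarray,
    classes: Sequence[str],
    positive_class: str | None = None,
    macro: bool = False,
) -> MetricsReport:
    """Argmax predictions on a split, summarised per the task's conventions."""
    if len(x) == 0:
        raise ValueError("cannot evaluate an empty split")
    y_pred = _predict_batched(model, x)
    cm = confusion_matrix(y, y_pred, n_classes=len(classes))
    if len(classes) == 2:
        pos = positive_class or positive_class_for(classes)
        report = metrics_from_confusion(cm, positive_index=list(classes).index(pos),
                                        positive_class=pos)
    else:
        report = metrics_from_confusion(cm)
        if macro:
            report.precision, report.recall = macro_precision_recall(cm)
    return report


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    """Outcome of a training run: best-on-validation model plus diagnostics."""

    model: ResidualNetwork | Module
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float
    stopped_early: bool
    config: TrainConfig
    task: str
    classes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        last = self.history.iloc[-1]
        lines = [
            f"task {self.task}: {len(self.history)} epochs "
            f"({'early stop' if self.stopped_early else 'completed'})",
            f"  best val accuracy {self.best_val_accuracy:.4f} at epoch {self.best_epoch}",
            f"  final train loss {last['train_loss']:.4f}, final lr {last['lr']:.2e}",
        ]
        return "\n".join(lines)


def train(
    model: Module,
    ds: SliceDataset,
    cfg: TrainConfig | None = None,
    task: str = "AD:MCI:HC",
    image_hw: tuple[int, int] | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Adam/cross-entropy training with plateau decay and early stopping.

    Validation accuracy is computed every epoch; the parameters achieving the
    best validation accuracy are restored into the model on return.
    """
    cfg = cfg or TrainConfig()
    x_train, y_train, classes = prepare_task(ds, task, split="train", image_hw=image_hw)
    x_val, y_val, _ = prepare_task(ds, task, split="val", image_hw=image_hw)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr0)
    scheduler = PlateauScheduler(cfg.lr0, patience=cfg.plateau_patience, factor=cfg.plateau_factor)
    stopper = EarlyStopping(patience=cfg.earlystop_patience)

    best_state: dict | None = None
    best_val, best_epoch = -np.inf, 0
    records = []
    stopped_early = False

    model.train()
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        losses, n_correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model(Tensor(x_train[idx]))
            loss = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={optimizer.lr:.2e}, batch index {i}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data) * len(idx))
            n_correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
        train_loss = float(np.sum(losses) / len(order))
        train_acc = n_correct / len(order)

        val_pred = _predict_batched(model, x_val, batch_size=max(cfg.batch_size, 64))
        val_acc = float((val_pred == y_val).mean())
        model.train()

        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}

        optimizer.lr = scheduler.step(val_acc)
        records.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_accuracy": train_acc,
                "val_accuracy": val_acc,
                "lr": optimizer.lr,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {train_loss:.4f}  "
                f"train acc {train_acc:.3f}  val acc {val_acc:.3f}  lr {optimizer.lr:.2e}"
            )
        if stopper.step(train_loss):
            stopped_early = True
            break

    if best_state is not None:
        model.load_state(best_state)
    model.eval()
    return TrainResult(
        model=model,
        history=pd.DataFrame.from_records(records),
        best_epoch=best_epoch,
        best_val_accuracy=float(best_val),
        stopped_early=stopped_early,
        config=cfg,
        task=task,
        classes=classes,
    )
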