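"""Training protocol and evaluation suite for the SSVEP classifier.

Per subject: the training trials are split 9:1 (class-stratified) into
train/validation, random windows are harvested from each trial and pushed
through the filter bank, and the network is optimized with Adam
(lr 8e-4, weight decay 0.01) on softmax cross-entropy.  One "iteration" is
one mini-batch step; batches are drawn by reshuffled cyclic passes over the
harvested windows.  Validation accuracy is measured on a fixed cadence and
the best-validation parameter state is returned.

Evaluation reports overall accuracy plus per-class one-vs-rest sensitivity,
specificity, precision and F1 (all in percent) from the 4x4 confusion
matrix; paired two-sided t-tests compare per-subject accuracies between
methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import preprocess
from .model import EEGResNet
from . import nn

__all__ = [
    "TrainConfig", "MetricsReport", "TTestResult",
    "split_trials", "harvest_windows", "train", "evaluate",
    "confusion_matrix", "metrics_from_confusion", "paired_t_test",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 8e-4
    weight_decay: float = 0.01
    batch_size: int = 250
    iterations: int = 2000
    windows_per_trial: int = 20
    split_ratio: tuple = (9, 1)
    eval_every: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.iterations,
               self.windows_per_trial, self.eval_every) < 0:
            raise ValueError("training parameters must be positive")
        if min(self.split_ratio) < 1:
            raise ValueError("split ratio parts must be >= 1")


@dataclass
class MetricsReport:
    """Accuracy and per-class one-vs-rest metrics, all on a 0-100 scale."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    df: int


def split_trials(labels, ratio=(9, 1), seed: int = 0):
    """Disjoint, exhaustive, class-stratified split of trial indices.

    ratio=(9, 1) sends 9/10 of each class to the training part; remainders
    are assigned to keep the overall proportions as close as possible.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    frac = ratio[0] / (ratio[0] + ratio[1])
    classes = np.unique(labels)
    counts = np.array([np.sum(labels == k) for k in classes])
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 trials to split")
    # largest-remainder allocation so the overall ratio is met exactly
    target_total = int(round(frac * len(labels)))
    base = np.floor(frac * counts).astype(int)
    base = np.clip(base, 1, counts - 1)
    remainder = frac * counts - base
    short = target_total - base.sum()
    for i in np.argsort(-remainder):
        if short <= 0:
            break
        if base[i] < counts[i] - 1:
            base[i] += 1
            short -= 1
    train_idx, val_idx = [], []
    for k, n_train in zip(classes, base):
        idx = np.flatnonzero(labels == k)
        rng.shuffle(idx)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def harvest_windows(trials, labels, ws: preprocess.WindowSpec,
                    windows_per_trial: int, rng: np.random.Generator,
                    bank=None, mode: str = "zero-phase"):
    """Draw random windows per trial, filter each through the bank.

    trials: (n, 9, samples) at 250 Hz.  Returns ((N, 4, 9, P), labels) with
    N = n * windows_per_trial; window labels inherit the trial labels.
    When bank is None the raw (N, 9, P) crops are returned (the form the CCA
    baselines consume).
    """
    trials = np.asarray(trials)
    labels = np.asarray(labels)
    crops, out_labels = [], []
    for trial, lab in zip(trials, labels):
        for _ in range(windows_per_trial):
            crops.append(preprocess.random_window(trial, ws, rng))
            out_labels.append(lab)
    crops = np.stack(crops)
    out_labels = np.asarray(out_labels)
    if bank is None:
        return crops, out_labels
    return preprocess.apply_filter_bank(crops, bank, mode=mode), out_labels


def train(model: EEGResNet, train_x, train_y, val_x, val_y,
          cfg: TrainConfig = TrainConfig()):
    """Optimize the network; returns (model restored to the best-validation
    state, history dict with loss / val accuracy curves)."""
    train_x = np.asarray(train_x, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(train_x)
    order = rng.permutation(n)
    pos = 0
    history = {"iteration": [], "loss": [], "val_iteration": [], "val_accuracy": []}
    best_acc, best_state = -1.0, model.get_state()
    for it in range(1, cfg.iterations + 1):
        take = min(cfg.batch_size, n)
        if pos + take > n:
            order = rng.permutation(n)
            pos = 0
        batch = order[pos:pos + take]
        pos += take
        logits = model.forward(train_x[batch], train=True)
        loss, dlogits = nn.cross_entropy_with_grad(logits, train_y[batch])
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        opt.zero_grad()
        model.backward(dlogits)
        opt.step()
        history["iteration"].append(it)
        history["loss"].append(loss)
        if it % cfg.eval_every == 0 or it == cfg.iterations:
            acc = float(np.mean(model.predict(val_x) == val_y)) * 100.0
            history["val_iteration"].append(it)
            history["val_accuracy"].append(acc)
            if acc > best_acc:
                best_acc = acc
                best_state = model.get_state()
    model.set_state(best_state)
    return model, history


def confusion_matrix(y_true, y_pred, n_classes: int = 4) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix with rows = true class."""
    cm = np.asarray(cm, dtype=np.int64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def _safe(num, den):
        den = np.asarray(den, dtype=float)
        out = np.zeros_like(den)
        nz = den > 0
        out[nz] = np.asarray(num, dtype=float)[nz] / den[nz]
        return out

    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    prec = _safe(tp, tp + fp)
    f1 = _safe(2 * prec * sens, prec + sens)
    return MetricsReport(
        confusion=cm,
        accuracy=float(tp.sum() / total) * 100.0,
        sensitivity=sens * 100.0,
        specificity=spec * 100.0,
        precision=prec * 100.0,
        f1=f1 * 100.0,
    )


def evaluate(predictions, labels) -> MetricsReport:
    """MetricsReport from predicted and true class indices."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty test set")
    return metrics_from_confusion(confusion_matrix(labels, predictions))


def paired_t_test(a, b) -> TTestResult:
    """Classical two-sided paired t-test on per-subject accuracies."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       n=len(a), df=len(a) - 1)
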