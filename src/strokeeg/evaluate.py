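"""Training protocol, subject-level cross-validation, and metrics.

Classification metrics follow the confusion-matrix definitions
(percentages): Acc = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(TN+FP).
AUC is the rank-statistic (Mann-Whitney concordance) form with midranks
for ties. Cross-validation folds split at the *subject* level so that no
subject contributes epochs to both sides of a split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError
from .nn.layers import Network, SGD, softmax_cross_entropy


@dataclass
class TrainConfig:
    """SGD training protocol.

    Defaults are the full-scale protocol (batch 512, learning rate 1e-4,
    up to 100 epochs, cross-entropy, early stopping on validation loss);
    ``desk_scale`` below returns a faster variant for small synthetic
    cohorts. The batch size is auto-capped at the dataset size.
    """

    batch_size: int = 512
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    momentum: float = 0.0
    weight_decay: float = 0.0   # L2 penalty on weight matrices
    lr_decay: float = 1.0       # per-epoch multiplicative decay of the rate
    loss_floor: float = 0.0     # stop once the training loss falls below this
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ParameterError("batch_size, max_epochs and patience must be >= 1")
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if not 0 < self.lr_decay <= 1:
            raise ParameterError("lr_decay must lie in (0, 1]")

    @staticmethod
    def desk_scale(seed: int = 0) -> "TrainConfig":
        return TrainConfig(batch_size=64, learning_rate=0.03, momentum=0.9,
                           lr_decay=0.85, max_epochs=12, patience=4,
                           loss_floor=0.08, seed=seed)


@dataclass
class TrainResult:
    network: Network
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    stopped_early: bool


@dataclass
class FoldResult:
    fold: int
    tp: int
    fn: int
    fp: int
    tn: int
    acc: float
    sen: float
    spe: float
    auc: float
    roc_fpr: list[float] = field(default_factory=list)
    roc_tpr: list[float] = field(default_factory=list)

    @property
    def n_eval(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    folds: list[FoldResult]
    mean_acc: float
    sd_acc: float
    mean_sen: float
    sd_sen: float
    mean_spe: float
    sd_spe: float
    mean_auc: float
    sd_auc: float
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "mean": {"acc": self.mean_acc, "sen": self.mean_sen,
                     "spe": self.mean_spe, "auc": self.mean_auc},
            "sd": {"acc": self.sd_acc, "sen": self.sd_sen,
                   "spe": self.sd_spe, "auc": self.sd_auc},
            "folds": [asdict(f) for f in self.folds],
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def make_folds(subject_ids: Sequence[str], labels: Sequence[int], k: int = 5,
               seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Subject-level stratified K-fold partitions.

    All epochs of a subject share a fold; every subject is tested exactly
    once. Raises if a test fold would miss a class entirely.
    """
    subject_ids = list(subject_ids)
    labels = np.asarray(labels)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if len(set(labels.tolist())) < 2:
        raise ParameterError("both classes must be present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(subject_ids, labels):
        if len(set(labels[test_idx].tolist())) < 2:
            warnings.warn(f"a test fold contains a single class "
                          f"({len(test_idx)} subjects)", UserWarning)
        folds.append(([subject_ids[i] for i in train_idx],
                      [subject_ids[i] for i in test_idx]))
    return folds


def make_epoch_folds_leakage_prone(n_epochs: int, labels: Sequence[int], k: int = 5,
                                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Epoch-level stratified folds, ignoring subject identity.

    Epochs of the same subject land on both sides of a split, so a
    classifier can score epochs of subjects it has already seen --
    optimistic by construction. Provided only for protocol comparisons;
    use :func:`make_folds` for honest evaluation.
    """
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train_idx, test_idx)
            for train_idx, test_idx in skf.split(np.zeros(n_epochs), labels)]


def train(network: Network, x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
          x_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None) -> TrainResult:
    """SGD training with cross-entropy loss and early stopping.

    Stops when the validation loss has not improved for ``cfg.patience``
    epochs (when a validation set is given) and restores the
    best-validation weights. Deterministic given ``cfg.seed``.
    """
    if len(x) == 0 or len(set(np.asarray(y).tolist())) < 2:
        raise ParameterError("training set must be non-empty with both labels")
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(network, cfg.learning_rate, cfg.momentum, cfg.weight_decay)
    batch = min(cfg.batch_size, len(x))

    def eval_loss(xe, ye) -> float:
        total, n = 0.0, 0
        for i in range(0, len(xe), 256):
            logits = network.forward(xe[i:i + 256])
            loss, _ = softmax_cross_entropy(logits, ye[i:i + 256])
            total += loss * len(xe[i:i + 256])
            n += len(xe[i:i + 256])
        return total / n

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_state = network.state_dict()
    best_epoch = 0
    since_best = 0
    stopped_early = False

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** epoch
        order = rng.permutation(len(x))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(x), batch):
            idx = order[i:i + batch]
            network.zero_grads()
            logits = network.forward(x[idx])
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise ParameterError(f"loss diverged (non-finite) at epoch {epoch}")
            network.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        train_losses.append(epoch_loss / seen)

        if x_val is not None and len(x_val):
            vl = eval_loss(np.ascontiguousarray(x_val, dtype=np.float32),
                           np.asarray(y_val, dtype=np.int64))
            val_losses.append(vl)
            if vl < best_val - 1e-12:
                best_val = vl
                best_state = network.state_dict()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    stopped_early = True
                    break
        else:
            best_state = network.state_dict()
            best_epoch = epoch
        if cfg.loss_floor > 0 and train_losses[-1] < cfg.loss_floor:
            stopped_early = True
            break

    network.load_state_dict(best_state)
    return TrainResult(network, train_losses, val_losses, best_epoch, stopped_early)


def metrics(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity as percentages.

    Sen/Spe are NaN (flagged undefined) when their denominator is zero.
    """
    for v in (tp, fn, fp, tn):
        if v < 0:
            raise ParameterError("confusion counts must be non-negative")
    total = tp + fn + fp + tn
    if total == 0:
        raise ParameterError("empty confusion matrix")
    acc = 100.0 * (tp + tn) / total
    sen = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spe = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return acc, sen, spe


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC points and the rank-statistic AUC (midranks for ties)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc))


def fold_result(fold: int, probs_class1: np.ndarray, labels: np.ndarray) -> FoldResult:
    """Confusion counts + metrics for one evaluated fold."""
    labels = np.asarray(labels)
    pred = (np.asarray(probs_class1) >= 0.5).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    acc, sen, spe = metrics(tp, fn, fp, tn)
    if len(set(labels.tolist())) == 2:
        roc = roc_auc(probs_class1, labels)
        auc, fprs, tprs = roc.auc, roc.fpr.tolist(), roc.tpr.tolist()
    else:
        auc, fprs, tprs = float("nan"), [], []
    return FoldResult(fold=fold, tp=tp, fn=fn, fp=fp, tn=tn,
                      acc=acc, sen=sen, spe=spe, auc=auc,
                      roc_fpr=fprs, roc_tpr=tprs)


def summarize(folds: list[FoldResult], seed: int = 0,
              provenance: dict | None = None) -> MetricsReport:
    def ms(vals):
        a = np.asarray(vals, dtype=np.float64)
        return float(np.nanmean(a)), float(np.nanstd(a))

    mean_acc, sd_acc = ms([f.acc for f in folds])
    mean_sen, sd_sen = ms([f.sen for f in folds])
    mean_spe, sd_spe = ms([f.spe for f in folds])
    mean_auc, sd_auc = ms([f.auc for f in folds])
    return MetricsReport(folds=folds, mean_acc=mean_acc, sd_acc=sd_acc,
                         mean_sen=mean_sen, sd_sen=sd_sen,
                         mean_spe=mean_spe, sd_spe=sd_spe,
                         mean_auc=mean_auc, sd_auc=sd_auc,
                         seed=seed, provenance=provenance or {})
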