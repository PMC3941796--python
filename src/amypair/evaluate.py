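"""Confusion statistics, ROC/AUC, and repeated stratified cross-validation.

Sensitivity Sn = TP/(TP+FN) and specificity Sp = TN/(TN+FP) are computed at
a decision threshold w_l with the strict rule "positive iff score > w_l".
The ROC curve sweeps the threshold over the observed score values (exact
step curve) and the AUC is obtained by trapezoidal integration of Sn
against 1-Sp, which equals the tie-corrected Mann-Whitney pairwise
concordance statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqcore import LabeledSequence
from .train import TrainedModel, TrainingConfig, fit
from .classify import score_sequences

logger = logging.getLogger(__name__)

#: Number of fixed specificity grid points used for vertical ROC averaging.
MEAN_ROC_GRID = 101


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn == 0:
            raise ValueError("no positive labels: sensitivity undefined")
        if self.tn + self.fp == 0:
            raise ValueError("no negative labels: specificity undefined")

    @property
    def sn(self) -> float:
        """Sensitivity TP/(TP+FN)."""
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        """Specificity TN/(TN+FP)."""
        return self.tn / (self.tn + self.fp)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_bool(labels: Sequence) -> np.ndarray:
    out = []
    for x in labels:
        if isinstance(x, str):
            if x not in ("positive", "negative", "pos", "neg", "+", "-"):
                raise ValueError(f"unknown label {x!r}")
            out.append(x in ("positive", "pos", "+"))
        else:
            out.append(bool(x))
    return np.array(out, dtype=bool)


def confusion(labels: Sequence, calls: Sequence) -> ConfusionCounts:
    """Confusion counts from true labels and predicted calls.

    Labels/calls may be booleans or any of {positive/negative, pos/neg, +/-}.
    """
    y = _as_bool(labels)
    c = _as_bool(calls)
    if y.size != c.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {c.size} calls")
    return ConfusionCounts(
        tp=int((y & c).sum()),
        fp=int((~y & c).sum()),
        fn=int((y & ~c).sum()),
        tn=int((~y & ~c).sum()),
    )


@dataclass
class ROCResult:
    """Threshold sweep (ascending) and the trapezoidal AUC."""

    points: List[Tuple[float, float, float]]  # (threshold w_l, Sn, Sp)
    auc: float

    def diagonal_point(self) -> Tuple[float, float, float]:
        """The sweep point minimizing |Sn - Sp| (the 'diagonal' operating
        point, where sensitivity and specificity balance)."""
        return min(self.points, key=lambda t: abs(t[1] - t[2]))


def roc_curve(scores: Sequence[float], labels: Sequence) -> ROCResult:
    """Exact step ROC over the observed scores, with the strict call rule
    score > threshold."""
    s = np.asarray(scores, dtype=float)
    y = _as_bool(labels)
    if s.size != y.size:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    thresholds = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    points = []
    for t in thresholds:
        calls = s > t
        tp = int((y & calls).sum())
        fp = int((~y & calls).sum())
        points.append((float(t), tp / n_pos, 1.0 - fp / n_neg))
    # ascending threshold: Sn non-increasing, Sp non-decreasing
    fpr = np.array([1.0 - sp for _, _, sp in points])
    tpr = np.array([sn for _, sn, _ in points])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCResult(points=points, auc=auc)


def stratified_folds(labels: Sequence, k: int,
                     rng: np.random.Generator) -> List[np.ndarray]:
    """Index sets of k folds preserving the positive:negative ratio."""
    y = _as_bool(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    folds: List[List[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    for f in out:
        fy = y[f]
        if fy.all() or (~fy).all():
            raise ValueError(
                "a fold has no positives or no negatives; lower the number "
                "of folds or rebalance the dataset"
            )
    return out


@dataclass
class CVResult:
    """Repeated stratified k-fold cross-validation summary."""

    folds: int
    repeats: int
    seed: int
    trial_aucs: List[float]
    mean_roc: List[Tuple[float, float]]  # (1-Sp grid, mean Sn)
    auc_mean: float
    quantiles: Dict[str, float]  # of the diagonal-point balanced accuracy
    diagonal_stats: List[float] = field(default_factory=list)


def _vertical_average(rocs: Sequence[ROCResult]) -> List[Tuple[float, float]]:
    """Average Sn at fixed 1-Sp grid points (linear interpolation)."""
    grid = np.linspace(0.0, 1.0, MEAN_ROC_GRID)
    curves = []
    for r in rocs:
        fpr = np.array([1.0 - sp for _, _, sp in r.points])[::-1]
        tpr = np.array([sn for _, sn, _ in r.points])[::-1]
        order = np.argsort(fpr, kind="stable")
        curves.append(np.interp(grid, fpr[order], tpr[order]))
    mean = np.mean(curves, axis=0)
    return list(zip(grid.tolist(), mean.tolist()))


def cross_validate(sequences: Sequence[LabeledSequence],
                   config: Optional[TrainingConfig] = None,
                   folds: int = 4, repeats: int = 10,
                   seed: int = 0) -> CVResult:
    """Repeated stratified k-fold CV: fit on k-1 folds, ROC on the held-out
    fold; folds x repeats independent trial AUCs.

    Bit-for-bit reproducible given (dataset order, seed).
    """
    if config is None:
        config = TrainingConfig()
    labels = [s.label for s in sequences]
    y = _as_bool(labels)
    rng = np.random.default_rng(seed)
    trial_aucs: List[float] = []
    diagonal_stats: List[float] = []
    rocs: List[ROCResult] = []
    for _ in range(repeats):
        fold_idx = stratified_folds(labels, folds, rng)
        for test_idx in fold_idx:
            test_mask = np.zeros(len(sequences), dtype=bool)
            test_mask[test_idx] = True
            train_pos = [s for s, m, p in zip(sequences, test_mask, y) if not m and p]
            train_neg = [s for s, m, p in zip(sequences, test_mask, y) if not m and not p]
            model = fit(train_pos, train_neg, config)
            test_seqs = [sequences[i] for i in test_idx]
            scores = score_sequences(test_seqs, model)
            roc = roc_curve(scores, [s.label for s in test_seqs])
            trial_aucs.append(roc.auc)
            _, sn, sp = roc.diagonal_point()
            diagonal_stats.append((sn + sp) / 2.0)
            rocs.append(roc)
    d = np.array(diagonal_stats)
    return CVResult(
        folds=folds,
        repeats=repeats,
        seed=seed,
        trial_aucs=trial_aucs,
        mean_roc=_vertical_average(rocs),
        auc_mean=float(np.mean(trial_aucs)),
        quantiles={
            "median": float(np.quantile(d, 0.5)),
            "q0.85": float(np.quantile(d, 0.85)),
            "q0.95": float(np.quantile(d, 0.95)),
        },
        diagonal_stats=diagonal_stats,
    )


def cross_test(train_set: Sequence[LabeledSequence],
               test_set: Sequence[LabeledSequence],
               config: Optional[TrainingConfig] = None,
               swap_labels: bool = False) -> ROCResult:
    """Fit on one dataset, ROC on another.

    ``swap_labels=True`` inverts the TEST labels, probing whether the
    negative class carries a discriminative pattern of its own (a biased
    negative set scores well above 0.5 under the swap).  Overlapping
    sequences between the two sets are logged, not rejected: disjointness
    is the caller's responsibility.
    """
    if config is None:
        config = TrainingConfig()
    train_strings = {s.residues.tobytes() for s in train_set}
    overlap = sum(1 for s in test_set if s.residues.tobytes() in train_strings)
    if overlap:
        logger.warning("%d test sequences also occur in the training set", overlap)
    y = _as_bool([s.label for s in train_set])
    model = fit([s for s, p in zip(train_set, y) if p],
                [s for s, p in zip(train_set, y) if not p], config)
    scores = score_sequences(test_set, model)
    labels = _as_bool([s.label for s in test_set])
    if swap_labels:
        labels = ~labels
    return roc_curve(scores, labels)
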