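"""Classification metrics, the CCP complexity index, and stratified CV.

Conventions follow the two-class soil-pest setting: MH (Melolontha
hippocastani, label 0) is the positive class, MM (M. melolontha, label 1)
the negative one.  Besides the usual confusion-matrix metrics and a
rank-based AUC, the module computes the Computational Complexity Parameter

    CCP = (T_P * S_g / T_D) * 100,

where T_P is processing time, T_D total dataset duration, and S_g the
segmentation ratio — CCP < 1 means faster than real time, and activity-based
segmentation lowers it through S_g.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import features as feat
from . import ffnet as ff
from .segmentation import Segment

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts with MH (label 0) as the positive class."""

    tp: int  # MH predicted MH
    tn: int  # MM predicted MM
    fp: int  # MM predicted MH
    fn: int  # MH predicted MM

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def row_normalized_percent(self) -> np.ndarray:
        """2x2 table of row percentages (true class in rows: MH, MM)."""
        rows = np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)
        sums = rows.sum(axis=1, keepdims=True)
        return 100.0 * rows / np.maximum(sums, 1.0)


@dataclass
class CCPInputs:
    t_p: float  # processing time, seconds
    t_d: float  # total dataset duration, seconds
    s_g: float  # segmentation ratio in [0, 1]

    def __post_init__(self) -> None:
        if self.t_p < 0:
            raise ValueError("t_p must be >= 0")
        if self.t_d <= 0:
            raise ValueError("t_d must be > 0")
        if not 0.0 <= self.s_g <= 1.0:
            raise ValueError("s_g must lie in [0, 1]")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    ccp: float | None = None
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.ccp is not None:
            d["ccp"] = self.ccp
        if self.confusion is not None:
            c = self.confusion
            d["confusion"] = {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
        return d


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Confusion counts; labels are 0 (MH) and 1 (MM)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 0) & (y_pred == 0))),
        tn=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 1) & (y_pred == 0))),
        fn=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 from confusion counts.

    A zero denominator yields 0 for that metric (with a warning) rather
    than an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den, name):
        if den == 0:
            log.warning("%s undefined (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return MetricsReport(accuracy, precision, recall, f1, confusion=cm)


def auc(scores, y_true) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties.

    `scores` rank label 1 high (larger score = more MM-like); both classes
    must be present.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    n1 = int(np.sum(y_true == 1))
    n0 = int(np.sum(y_true == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks give the tie credit
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def ccp(inputs: CCPInputs | float, s_g: float | None = None, t_d: float | None = None) -> float:
    """Computational Complexity Parameter ``(T_P * S_g / T_D) * 100``."""
    if not isinstance(inputs, CCPInputs):
        inputs = CCPInputs(float(inputs), float(t_d), float(s_g))
    return inputs.t_p * inputs.s_g / inputs.t_d * 100.0


@dataclass
class FoldPlan:
    """Stratified assignment of samples to k folds."""

    k: int
    assignment: np.ndarray  # sample index -> fold index
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Per-class shuffled round-robin fold assignment.

    Deterministic for a given seed; per-class counts differ by at most one
    across folds.  Every class must have at least k samples.
    """
    labels = np.asarray(labels)
    assignment = np.full(labels.size, -1, dtype=int)
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} samples, fewer than k={k}")
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    t_p: float  # feature extraction + inference time over evaluated segments
    plan: FoldPlan

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports]))


def cross_validate(
    segments: list[Segment],
    config: ff.TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    total_duration_s: float | None = None,
    s_g: float = 1.0,
) -> CVResult:
    """Stratified k-fold CV of the full feature + forward-forward pipeline.

    The min-max feature scaler is fitted on each fold's training partition
    only.  The pooled report aggregates out-of-fold predictions; its CCP
    uses the measured feature-extraction + inference time (training
    excluded, per the default CCP convention) with the supplied
    segmentation ratio `s_g` and dataset duration.
    """
    config = config or ff.TrainConfig()
    labels = np.array([s.label for s in segments])
    plan = stratified_kfold(labels, k=k, seed=seed)
    t0 = time.perf_counter()
    matrices = [feat.mfcc(s) for s in segments]
    t_features = time.perf_counter() - t0
    t_infer = 0.0
    fold_reports = []
    all_pred = np.empty(labels.size, dtype=int)
    all_margin = np.empty(labels.size)
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        pos, neg, scaler = feat.make_training_pairs([matrices[i] for i in tr])
        net = ff.train_network((pos, neg), config, scaler=scaler)
        net.scaler = scaler
        t0 = time.perf_counter()
        pred, margin = net.predict_batch([matrices[i] for i in te])
        t_infer += time.perf_counter() - t0
        all_pred[te], all_margin[te] = pred, margin
        report = metrics(confusion(labels[te], pred))
        report.auc = auc(margin, labels[te])
        fold_reports.append(report)
        log.info("fold %d: accuracy %.3f auc %.3f", fold, report.accuracy, report.auc)
    t_p = t_features + t_infer
    pooled = metrics(confusion(labels, all_pred))
    pooled.auc = auc(all_margin, labels)
    if total_duration_s is not None:
        pooled.ccp = ccp(CCPInputs(t_p=t_p, t_d=total_duration_s, s_g=s_g))
    return CVResult(fold_reports=fold_reports, pooled=pooled, t_p=t_p, plan=plan)


def write_report(result: CVResult, path) -> None:
    """Metrics as JSON plus a per-fold TSV next to it."""
    from pathlib import Path

    path = Path(path)
    payload = {
        "pooled": result.pooled.to_dict(),
        "mean_fold_accuracy": result.mean_accuracy,
        "t_p_seconds": result.t_p,
        "folds": [r.to_dict() for r in result.fold_reports],
    }
    path.write_text(json.dumps(payload, indent=2))
    tsv = path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        fh.write("fold\taccuracy\tprecision\trecall\tf1\tauc\n")
        for i, r in enumerate(result.fold_reports):
            fh.write(
                f"{i}\t{r.accuracy:.4f}\t{r.precision:.4f}\t{r.recall:.4f}"
                f"\t{r.f1:.4f}\t{r.auc:.4f}\n"
            )
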