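"""Confusion-matrix metrics, ROC/AUC and cross-validation orchestration.

Cross-validation is leakage-safe by default: within every fold the
position-probability matrices and the log-odds score matrix are rebuilt
from the training samples only, and the held-out fold is featurized with
that training matrix. Held-out scores from all folds are pooled into one
confusion matrix and one ROC curve (leave-one-out forces pooling; the same
convention is applied to k-fold for comparability). A ``global_ppm`` switch
reproduces the leaky variant — PPMs computed once on all data — for
sensitivity comparisons only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .classifier import ForestConfig, score_features, train
from .features import FeatureSpec, build_score_matrix, featurize, labeled_feature_matrix
from .seqio import SequenceSet

logger = logging.getLogger(__name__)

STRINGENT_CUTOFF = 0.667


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, true: np.ndarray, pred: np.ndarray) -> "ConfusionCounts":
        true = np.asarray(true)
        pred = np.asarray(pred)
        return cls(
            tp=int(np.sum((true == 1) & (pred == 1))),
            fp=int(np.sum((true == -1) & (pred == 1))),
            tn=int(np.sum((true == -1) & (pred == -1))),
            fn=int(np.sum((true == 1) & (pred == -1))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity/specificity/accuracy as percentages, MCC in [-1, 1]."""

    sn: float
    sp: float
    ac: float
    mcc: float
    mcc_undefined: bool = False
    auc: float | None = None

    def formatted(self) -> dict[str, str]:
        """Percentages to 2 decimals, MCC to 4 — the conventional table format."""
        out = {"Sn": f"{self.sn:.2f}", "Sp": f"{self.sp:.2f}",
               "Ac": f"{self.ac:.2f}", "MCC": f"{self.mcc:.4f}"}
        if self.auc is not None:
            out["AUC"] = f"{self.auc:.4f}"
        return out


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total (as percentages),
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).

    A zero MCC marginal makes the coefficient undefined; it is reported as 0
    with ``mcc_undefined=True``.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("need at least one evaluated sample of each class")
    sn = 100.0 * c.tp / (c.tp + c.fn)
    sp = 100.0 * c.tn / (c.tn + c.fp)
    ac = 100.0 * (c.tp + c.tn) / c.total
    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return MetricSet(sn=sn, sp=sp, ac=ac, mcc=0.0, mcc_undefined=True)
    mcc = (c.tp * c.tn - c.fn * c.fp) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC by sweeping the threshold over distinct scores; AUC by the
    trapezoidal rule (equals the tie-corrected Mann–Whitney concordance)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    present = set(np.unique(labels))
    if present != {-1, 1}:
        raise ValueError("ROC needs both classes among the labels")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, pos_label=1)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(np.trapezoid(tpr, fpr)))


@dataclass(frozen=True)
class CVPlan:
    """k-fold (any k >= 2) or leave-one-out, stratified by class, seeded."""

    scheme: int | Literal["loo"] = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.scheme != "loo" and (not isinstance(self.scheme, int) or self.scheme < 2):
            raise ValueError("scheme must be 'loo' or an integer k >= 2")


@dataclass
class EvaluationReport:
    """Pooled held-out performance plus a per-fold breakdown."""

    scheme: str
    n_pos: int
    n_neg: int
    scores: np.ndarray          # pooled held-out scores, dataset order
    labels: np.ndarray          # matching true labels {+1,-1}
    pooled: dict[str, MetricSet]  # keyed by cutoff, e.g. "0.5", "0.667"
    roc: RocCurve
    fold_metrics: list[MetricSet] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return self.roc.auc

    def confusion(self, cutoff: float = 0.5) -> ConfusionCounts:
        pred = np.where(self.scores >= cutoff, 1, -1)
        return ConfusionCounts.from_labels(self.labels, pred)

    def to_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "auc": round(self.auc, 6),
            "pooled": {},
            "per_fold": [],
        }
        for cutoff, ms in self.pooled.items():
            c = self.confusion(float(cutoff))
            out["pooled"][cutoff] = {
                "TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn,
                "Sn": round(ms.sn, 2), "Sp": round(ms.sp, 2),
                "Ac": round(ms.ac, 2), "MCC": round(ms.mcc, 4),
                "mcc_undefined": ms.mcc_undefined,
            }
        for ms in self.fold_metrics:
            out["per_fold"].append({
                "Sn": round(ms.sn, 2), "Sp": round(ms.sp, 2),
                "Ac": round(ms.ac, 2), "MCC": round(ms.mcc, 4),
            })
        return out


def _fold_indices(labels: np.ndarray, plan: CVPlan):
    n = len(labels)
    if plan.scheme == "loo":
        for i in range(n):
            test = np.array([i])
            yield np.setdiff1d(np.arange(n), test), test
    elif plan.stratified:
        splitter = StratifiedKFold(n_splits=plan.scheme, shuffle=True, random_state=plan.seed)
        yield from splitter.split(np.zeros(n), labels)
    else:
        rng = np.random.default_rng(plan.seed)
        order = rng.permutation(n)
        for chunk in np.array_split(order, plan.scheme):
            yield np.setdiff1d(np.arange(n), chunk), chunk


def cross_validate(
    pos: SequenceSet,
    neg: SequenceSet,
    plan: CVPlan = CVPlan(),
    cfg: ForestConfig = ForestConfig(),
    feature_spec: FeatureSpec = FeatureSpec(),
    cutoffs: tuple[float, ...] = (0.5, STRINGENT_CUTOFF),
    global_ppm: bool = False,
) -> EvaluationReport:
    """Cross-validated evaluation with fold-local featurization.

    Every sample is held out exactly once; pooled held-out scores give the
    headline confusion matrices (at each cutoff) and the ROC/AUC. Per-fold
    metric rows are reported for k-fold schemes (single-sample LOO folds
    have no meaningful confusion matrix of their own).
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both positive and negative sets must be non-empty")
    records = list(pos.records) + list(neg.records)
    labels = np.array([1] * len(pos) + [-1] * len(neg))
    if global_ppm:
        logger.warning(
            "global_ppm=True leaks held-out labels into the score matrix; "
            "use only for sensitivity comparisons"
        )
        shared_matrix = build_score_matrix(
            pos, neg, window=feature_spec.window, pseudocount=feature_spec.pseudocount
        )
    pooled_scores = np.full(len(records), np.nan)
    fold_metrics: list[MetricSet] = []
    seed_seq = np.random.SeedSequence(cfg.seed)
    for fold_no, (train_idx, test_idx) in enumerate(_fold_indices(labels, plan)):
        train_labels = labels[train_idx]
        if len(set(train_labels)) < 2:
            raise ValueError(
                f"fold {fold_no}: training split contains a single class "
                "(enable stratification or use fewer folds)"
            )
        tr_pos = SequenceSet([records[i] for i in train_idx if labels[i] == 1], "positive")
        tr_neg = SequenceSet([records[i] for i in train_idx if labels[i] == -1], "negative")
        te = SequenceSet([records[i] for i in test_idx])
        if feature_spec.kind in ("ppm", "both"):
            matrix = shared_matrix if global_ppm else build_score_matrix(
                tr_pos, tr_neg, window=feature_spec.window,
                pseudocount=feature_spec.pseudocount,
            )
        else:
            matrix = None
        fm_train = labeled_feature_matrix(tr_pos, tr_neg, feature_spec, matrix)
        fold_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % 2**31)
        model = train(fm_train, ForestConfig(
            n_trees=cfg.n_trees, features_per_split=cfg.features_per_split,
            seed=fold_seed, class_weighting=cfg.class_weighting,
        ), score_matrix=matrix, feature_spec=feature_spec)
        fm_test = featurize(te, feature_spec, matrix)
        if fm_test.n_samples != len(test_idx):
            raise ValueError(
                f"fold {fold_no}: {len(test_idx) - fm_test.n_samples} held-out "
                f"sequence(s) shorter than the window cannot be scored"
            )
        fold_scores = score_features(model, fm_test)
        pooled_scores[test_idx] = fold_scores
        if plan.scheme != "loo" and len(set(labels[test_idx])) == 2:
            pred = np.where(fold_scores >= cutoffs[0], 1, -1)
            fold_metrics.append(metrics(ConfusionCounts.from_labels(labels[test_idx], pred)))
    assert not np.isnan(pooled_scores).any(), "every sample must be scored exactly once"
    pooled = {}
    for cutoff in cutoffs:
        pred = np.where(pooled_scores >= cutoff, 1, -1)
        pooled[str(cutoff)] = metrics(ConfusionCounts.from_labels(labels, pred))
    roc = roc_auc(pooled_scores, labels)
    scheme_name = "loo" if plan.scheme == "loo" else f"{plan.scheme}-fold"
    return EvaluationReport(
        scheme=scheme_name, n_pos=len(pos), n_neg=len(neg),
        scores=pooled_scores, labels=labels, pooled=pooled, roc=roc,
        fold_metrics=fold_metrics,
    )
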