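"""Classification metrics and the repeated-experiment harness.

The essential class is the positive class throughout.  Scalar metrics
follow the standard confusion-matrix definitions

    Sn  = TP / (TP + FN)        Sp  = TN / (FP + TN)
    PPV = TP / (TP + FP)        Acc = (TP + TN) / (TP + FN + TN + FP)

with a classification threshold of 0.5 (probability ties classify as
positive).  A metric whose denominator is zero is reported as None —
undefined, never coerced to 0 — so aggregates are not silently skewed.

ROC/AUC and precision-recall/AUPR use the threshold-sweep curves of
scikit-learn; AUPR uses the step-wise (interpolation-free) summation
convention.  The repeated-experiment harness mirrors the evaluation
protocol of the original study: k seeded splits (random 80/10/10
selection repeated, or cluster-aware), one model trained per split,
metrics on the held-out test partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean, stdev

import numpy as np
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from . import mlp
from .datasets import DatasetSplit, Standardizer, split_records
from .errors import InvalidInputError
from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """All metrics of one evaluation, plus the curves behind the areas."""

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    accuracy: float | None
    roc: list[tuple[float, float]]
    auc: float
    pr: list[tuple[float, float]]
    aupr: float
    threshold: float = DEFAULT_THRESHOLD
    extras: dict = field(default_factory=dict)

    def scalars(self) -> dict[str, float | None]:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
        }


def _as_arrays(probs, labels):
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise InvalidInputError(
            f"probability/label length mismatch: {p.shape} vs {y.shape}"
        )
    return p, y


def confusion_at_threshold(
    probs, labels, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionCounts:
    """Tally confusion counts; prob >= threshold predicts essential."""
    p, y = _as_arrays(probs, labels)
    pred = p >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        TN=int(np.sum(~pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        log.warning("%s undefined (zero denominator); reported as missing", name)
        return None
    return num / den


def scalar_metrics(c: ConfusionCounts):
    """(Sn, Sp, PPV, accuracy); zero-denominator metrics come back None."""
    sn = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    sp = _ratio(c.TN, c.FP + c.TN, "specificity")
    ppv = _ratio(c.TP, c.TP + c.FP, "PPV")
    acc = _ratio(c.TP + c.TN, c.total, "accuracy")
    return sn, sp, ppv, acc


def roc_auc(probs, labels):
    """ROC points (FPR, TPR) over all thresholds and the trapezoidal AUC.

    Tie handling follows the standard sweep, so the AUC equals the
    pairwise statistic P(score_pos > score_neg) + 0.5 P(tie) exactly.
    """
    p, y = _as_arrays(probs, labels)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def pr_aupr(probs, labels):
    """Precision-recall points and the step-wise (no interpolation) AUPR."""
    p, y = _as_arrays(probs, labels)
    if int(np.sum(y == 1)) == 0:
        raise InvalidInputError("precision-recall requires at least one positive")
    precision, recall, _ = precision_recall_curve(y, p)
    points = list(zip(recall.tolist(), precision.tolist()))
    return points, float(average_precision_score(y, p))


def evaluate(probs, labels, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Full metrics report for one set of predictions."""
    counts = confusion_at_threshold(probs, labels, threshold)
    sn, sp, ppv, acc = scalar_metrics(counts)
    roc_points, auc_value = roc_auc(probs, labels)
    pr_points, aupr_value = pr_aupr(probs, labels)
    return MetricsReport(
        counts=counts,
        sensitivity=sn,
        specificity=sp,
        ppv=ppv,
        accuracy=acc,
        roc=roc_points,
        auc=auc_value,
        pr=pr_points,
        aupr=aupr_value,
        threshold=threshold,
    )


def _matrix(frame, records):
    idx = frame.set_index("gene_id")
    ids = [r.gene_id for r in records]
    x = idx.loc[ids, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = idx.loc[ids, "essential"].to_numpy(dtype=int)
    return x, y


def run_single_experiment(
    feature_frame,
    split: DatasetSplit,
    model_config: mlp.ModelConfig,
) -> MetricsReport:
    """Standardize, train, and evaluate one split; test-set report.

    The report's ``extras`` carries the validation-set AUC and the epoch
    training stopped at, since published aggregates do not always say
    which partition they were measured on.
    """
    x_train, y_train = _matrix(feature_frame, split.train)
    x_val, y_val = _matrix(feature_frame, split.validation)
    x_test, y_test = _matrix(feature_frame, split.test)
    scaler = Standardizer().fit(x_train)
    model = mlp.build_model(model_config)
    model = mlp.train(
        model,
        scaler.transform(x_train), y_train,
        scaler.transform(x_val), y_val,
    )
    test_probs = mlp.predict_proba(model, scaler.transform(x_test))
    report = evaluate(test_probs, y_test)
    val_probs = mlp.predict_proba(model, scaler.transform(x_val))
    _, val_auc = roc_auc(val_probs, y_val)
    report.extras = {"validation_auc": val_auc, "stopped_epoch": model.stopped_epoch}
    return report


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation of every scalar metric, plus raw AUCs."""
    agg: dict = {"n_repetitions": len(reports), "auc_values": [r.auc for r in reports]}
    for name in ("auc", "aupr", "sensitivity", "specificity", "ppv", "accuracy"):
        values = [r.scalars()[name] for r in reports if r.scalars()[name] is not None]
        agg[f"{name}_mean"] = mean(values) if values else None
        agg[f"{name}_sd"] = stdev(values) if len(values) > 1 else 0.0
    return agg


def repeated_experiment(
    records,
    feature_frame,
    policy: str = "random",
    n_repetitions: int = 10,
    base_seed: int = 0,
    model_config: mlp.ModelConfig | None = None,
    fractions=(0.8, 0.1, 0.1),
):
    """Repeat split -> train -> test-evaluate with seeds base_seed+k.

    Returns (list of MetricsReport, aggregate dict).  The corpus should
    already be class-balanced.
    """
    model_config = model_config or mlp.ModelConfig()
    reports = []
    for k in range(n_repetitions):
        seed = base_seed + k
        try:
            split = split_records(records, policy, fractions, seed)
            cfg = mlp.ModelConfig(**{**model_config.__dict__, "seed": seed})
            reports.append(run_single_experiment(feature_frame, split, cfg))
        except Exception as exc:
            raise type(exc)(f"repetition {k} (seed {seed}): {exc}") from exc
        log.info(
            "repetition %d (%s): test AUC %.4f", k, policy, reports[-1].auc
        )
    return reports, aggregate_reports(reports)
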