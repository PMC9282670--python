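"""Classifier evaluation calculus and validation protocols.

Implements the confusion-matrix metric set (sensitivity, specificity,
precision, accuracy), the single-operating-point AUC

    AUC = (1 - specificity) * sensitivity / 2 + (sensitivity + 1) * specificity / 2,

which is the area under the two-segment ROC polyline through the operating
point ``(1 - specificity, sensitivity)``, its normal-approximation CI
``AUC +/- 1.96 * sqrt(AUC * (1 - AUC) / N)``, and the full trapezoidal ROC
AUC over all thresholds.  Two protocols wrap these: a 70:30 hold-out
comparison (training and testing metrics per model, single-operating-point
AUC) and stratified k-fold cross-validation (pooled out-of-fold
probabilities, full ROC AUC).

Class imbalance (about 19% positives at the 0.88-logit cutoff) is handled
by a balanced operating point: the decision threshold is the midpoint of
the two class-conditional mean predicted probabilities of the set being
scored, so sensitivity and specificity are reported on comparable footing.
A fixed 0.5 threshold is available via ``balanced=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import classify as _classify_mod  # noqa: F401
from .classify import KINDS, classify as apply_threshold, predict_proba, train as train_model
from .cohort import Cohort, SplitSpec, make_folds, split_holdout

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EvalRecord",
    "ComparisonReport",
    "confusion",
    "metrics",
    "point_auc",
    "auc_ci",
    "full_roc_auc",
    "balanced_threshold",
    "evaluate_holdout",
    "evaluate_kfold",
]

Z_95 = 1.96


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a 2x2 confusion table."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """One classifier x one data split.  Undefined metrics are ``None``."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    auc: float | None
    se_auc: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "sensitivity", "specificity", "precision", "accuracy",
            "auc", "se_auc", "ci_low", "ci_high",
        )}


def confusion(pred_labels: Sequence[int], true_labels: Sequence[int]) -> ConfusionCounts:
    """Tally the 2x2 confusion table (positive class = 1)."""
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def point_auc(sensitivity: float, specificity: float) -> float:
    """Area under the two-segment ROC through one operating point."""
    return (1.0 - specificity) * sensitivity / 2.0 + (sensitivity + 1.0) * specificity / 2.0


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity/specificity/precision/accuracy plus the one-point AUC."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.n)
    auc = point_auc(sens, spec) if sens is not None and spec is not None else None
    return MetricSet(sensitivity=sens, specificity=spec, precision=prec, accuracy=acc, auc=auc)


def auc_ci(auc: float, n: int) -> tuple[float, float, float]:
    """Normal-approximation SE and 95% CI for an AUC on N cases.

    ``SE = sqrt(AUC * (1 - AUC) / N)``; bounds clipped to [0, 1].
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    se = float(np.sqrt(auc * (1.0 - auc) / n))
    lo = max(0.0, auc - Z_95 * se)
    hi = min(1.0, auc + Z_95 * se)
    return se, lo, hi


def full_roc_auc(probabilities: Sequence[float], true_labels: Sequence[int]) -> float:
    """Trapezoidal ROC AUC over all thresholds (Mann-Whitney concordance)."""
    y = np.asarray(true_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("full ROC AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def balanced_threshold(probabilities: np.ndarray, true_labels: np.ndarray) -> float:
    """Midpoint of the class-conditional mean predicted probabilities."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_labels)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("balanced threshold needs both classes present")
    return float((p[y == 1].mean() + p[y == 0].mean()) / 2.0)


@dataclass
class EvalRecord:
    """Metrics for one model on one split."""

    model: str
    split: str  # "train" | "test" | "kfold"
    n: int
    metrics: MetricSet
    threshold: float | None = None


@dataclass
class ComparisonReport:
    """Per model x split metric sets over identical data splits."""

    records: list[EvalRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def get(self, model: str, split: str) -> MetricSet:
        for r in self.records:
            if r.model == model and r.split == split:
                return r.metrics
        raise KeyError((model, split))

    def significance(self) -> dict[tuple[str, str], list[str]]:
        """Per (model, split): models in the same split whose 95% AUC CIs
        do not overlap this model's CI."""
        out: dict[tuple[str, str], list[str]] = {}
        for r in self.records:
            flags = []
            for other in self.records:
                if other.split != r.split or other.model == r.model:
                    continue
                m, o = r.metrics, other.metrics
                if None in (m.ci_low, m.ci_high, o.ci_low, o.ci_high):
                    continue
                if m.ci_low > o.ci_high or m.ci_high < o.ci_low:
                    flags.append(other.model)
            out[(r.model, r.split)] = flags
        return out

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"model": r.model, "split": r.split, "n": r.n, **r.metrics.to_dict()}
            rows.append(row)
        df = pd.DataFrame(rows)
        if decimals is not None:
            num = df.select_dtypes("number").columns.difference(["n"])
            df[num] = df[num].round(decimals)
        return df

    def to_json(self, path: str | Path) -> None:
        sig = {f"{m}/{s}": v for (m, s), v in self.significance().items()}
        doc = {
            "meta": self.meta,
            "records": [
                {
                    "model": r.model,
                    "split": r.split,
                    "n": r.n,
                    "threshold": r.threshold,
                    **r.metrics.to_dict(),
                }
                for r in self.records
            ],
            "significance": sig,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _with_ci(mset: MetricSet, n: int) -> MetricSet:
    if mset.auc is None:
        return mset
    se, lo, hi = auc_ci(mset.auc, n)
    return MetricSet(**{**mset.to_dict(), "se_auc": se, "ci_low": lo, "ci_high": hi})


def _operating_metrics(probs: np.ndarray, labels: np.ndarray, balanced: bool) -> tuple[MetricSet, float]:
    thr = balanced_threshold(probs, labels) if balanced else 0.5
    pred = apply_threshold(probs, threshold=thr)
    return metrics(confusion(pred, labels)), thr


def evaluate_holdout(
    cohort: Cohort,
    split: SplitSpec | None = None,
    kinds: Sequence[str] = KINDS,
    knn_k: int = 1,
    balanced: bool = True,
) -> ComparisonReport:
    """Hold-out comparison: train on the training fraction, report metrics
    on both sets with single-operating-point AUC and its CI."""
    split = split or SplitSpec()
    train_c, test_c = split_holdout(cohort, split)
    report = ComparisonReport(
        meta={
            "protocol": "holdout",
            "train_fraction": split.train_fraction,
            "n_train": train_c.n,
            "n_test": test_c.n,
            "knn_k": knn_k,
            "balanced": balanced,
            "seed": split.seed,
        }
    )
    for kind in kinds:
        model = train_model(kind, train_c.responses, train_c.labels, knn_k=knn_k)
        for name, part in (("train", train_c), ("test", test_c)):
            probs = predict_proba(model, part.responses)
            mset, thr = _operating_metrics(probs, part.labels, balanced)
            report.records.append(
                EvalRecord(
                    model=kind, split=name, n=part.n,
                    metrics=_with_ci(mset, part.n), threshold=thr,
                )
            )
    return report


def evaluate_kfold(
    cohort: Cohort,
    split: SplitSpec | None = None,
    kinds: Sequence[str] = KINDS,
    knn_k: int = 1,
    balanced: bool = True,
) -> ComparisonReport:
    """k-fold cross-validation: pool out-of-fold predicted probabilities,
    report confusion metrics at the balanced operating point and the full
    trapezoidal ROC AUC with CI at N = cohort size.

    The default ``knn_k`` of 1 (nearest neighbour) follows the Weka IBk
    convention; note that with k = 1 a model scored on its own training set
    predicts every row perfectly (the self row is not excluded).
    """
    split = split or SplitSpec()
    folds = make_folds(cohort, split)
    pos_of_id = {int(i): ix for ix, i in enumerate(cohort.ids)}
    report = ComparisonReport(
        meta={
            "protocol": "kfold",
            "folds": split.folds,
            "stratified": split.stratified,
            "n": cohort.n,
            "knn_k": knn_k,
            "balanced": balanced,
            "seed": split.seed,
        }
    )
    for kind in kinds:
        pooled = np.full(cohort.n, np.nan)
        for train_c, test_c in folds:
            model = train_model(kind, train_c.responses, train_c.labels, knn_k=knn_k)
            probs = predict_proba(model, test_c.responses)
            for i, p in zip(test_c.ids, probs):
                pooled[pos_of_id[int(i)]] = p
        assert not np.any(np.isnan(pooled)), "every case must be predicted once"
        mset, thr = _operating_metrics(pooled, cohort.labels, balanced)
        auc = full_roc_auc(pooled, cohort.labels)
        se, lo, hi = auc_ci(auc, cohort.n)
        mset = MetricSet(
            **{**mset.to_dict(), "auc": auc, "se_auc": se, "ci_low": lo, "ci_high": hi}
        )
        report.records.append(
            EvalRecord(model=kind, split="kfold", n=cohort.n, metrics=mset, threshold=thr)
        )
    return report
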