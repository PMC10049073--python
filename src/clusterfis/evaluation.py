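"""Data partitioning, classification metrics and McNemar's paired test.

Conventions follow the clinical framing of the case study: the *positive*
class is benign (label 1), so sensitivity is the benign recall and
specificity the malignant recall.  AUC for a hard classifier is defined as
(sensitivity + specificity) / 2, i.e. balanced accuracy.  McNemar's test
compares two classifiers through their discordant prediction counts b and c,
with chi-square significance at 3.84 (alpha = 0.05, 1 df).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_io import RecordTable

logger = logging.getLogger(__name__)

#: Chi-square critical value at alpha = 0.05 with 1 degree of freedom.
MCNEMAR_CRITICAL = 3.84


@dataclass
class PartitionPlan:
    """How to split records for training and validation.

    ``random_sampling`` draws ``iterations`` independent train/validation(/
    test) splits with the given fractions; ``kfold`` makes one pass of
    k-fold cross-validation.
    """

    scheme: str = "random_sampling"  # or "kfold"
    fractions: tuple[float, float, float] = (0.7, 0.3, 0.0)
    k: int = 10
    iterations: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("random_sampling", "kfold"):
            raise ValueError(f"unknown partition scheme {self.scheme!r}")
        fr = self.fractions
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must be non-negative and sum to 1: {fr}")
        if self.k < 2:
            raise ValueError("k-fold needs k >= 2")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion matrix with benign (class 1) as the positive class."""

    tp: int  # true benign,   predicted benign
    fn: int  # true benign,   predicted malignant
    fp: int  # true malignant, predicted benign
    tn: int  # true malignant, predicted malignant

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The six performance metrics derived from a confusion matrix.

    Ratios with a zero denominator are reported as nan and listed in
    ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f_measure: float
    auc: float
    kappa: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "kappa": self.kappa,
        }


@dataclass(frozen=True)
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float
    significant: bool
    corrected: bool = True


def shuffle_records(table: RecordTable, seed: int) -> RecordTable:
    """Random row permutation preserving feature-label pairing."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_records)
    return replace(
        table,
        features=table.features[perm],
        labels=table.labels[perm],
        ids=None if table.ids is None else table.ids[perm],
        missing_mask=None if table.missing_mask is None else table.missing_mask[perm],
    )


def random_partition(n: int, plan: PartitionPlan, seed: int | None = None):
    """Split indices 0..n-1 into disjoint (train, validation, test) sets.

    Validation and test sizes are round(n * fraction) (half rounds up); the
    remainder goes to train.  For the default 70/30/0 split of 699 records
    this yields 489 train and 210 validation.
    """
    if plan.scheme != "random_sampling":
        raise ValueError("random_partition requires a random_sampling plan")
    _, f_val, f_test = plan.fractions
    n_val = int(math.floor(n * f_val + 0.5))
    n_test = int(math.floor(n * f_test + 0.5))
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ValueError(
            f"fractions {plan.fractions} leave no training records for n={n}"
        )
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def kfold_partition(n: int, k: int, seed: int):
    """k-fold split: list of (train, validation) index pairs.

    Fold sizes differ by at most one; every index lands in exactly one
    validation fold.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} records")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    pairs = []
    for i in range(k):
        val = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        pairs.append((train, val))
    return pairs


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Tally the 2x2 matrix; labels must be in {1, 2}, benign = positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    foreign = set(np.unique(np.concatenate([y_true, y_pred]))) - {1, 2}
    if foreign:
        raise ValueError(f"labels must be in {{1, 2}}; found {sorted(foreign)}")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 2))),
        fp=int(np.sum((y_true == 2) & (y_pred == 1))),
        tn=int(np.sum((y_true == 2) & (y_pred == 2))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity, F-measure, AUC and Cohen's kappa.

    kappa = (p_o - p_e) / (1 - p_e) with the expected agreement p_e taken
    from the row/column marginal products.  AUC is the hard-classifier
    balanced accuracy (sensitivity + specificity) / 2.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.total
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (tp + tn) / n
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        undefined.append("f_measure")
        f_measure = float("nan")
    else:
        f_measure = 2 * precision * sensitivity / (precision + sensitivity)
    auc = (sensitivity + specificity) / 2.0

    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
    if p_e == 1.0:
        undefined.append("kappa")
        kappa = float("nan")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        f_measure=f_measure,
        auc=auc,
        kappa=kappa,
        undefined=tuple(undefined),
    )


def mcnemar_test(y_true, pred_a, pred_b, corrected: bool = True) -> McNemarResult:
    """McNemar's chi-square test on paired classifier predictions.

    b = records classifier A gets right and B wrong; c the reverse.  The
    continuity-corrected statistic is (|b - c| - 1)^2 / (b + c), floored at
    0; uncorrected is (b - c)^2 / (b + c).  b + c = 0 gives statistic 0.
    Significance at the 3.84 threshold (alpha = 0.05, 1 df).
    """
    y_true = np.asarray(y_true)
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    if not (y_true.shape == pred_a.shape == pred_b.shape):
        raise ValueError("prediction vectors must match y_true in length")
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        stat = 0.0
    elif corrected:
        stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    return McNemarResult(
        b=b,
        c=c,
        statistic=float(stat),
        significant=stat > MCNEMAR_CRITICAL,
        corrected=corrected,
    )
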