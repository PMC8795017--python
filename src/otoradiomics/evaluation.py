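"""Evaluation protocols and diagnostic-test metrics.

Two protocols mirror the study design: a center-aware 74/26 train-test split
in which one center is held out entirely as an external test site (its ears
complemented with randomly drawn ears from the remaining centers), and a
stratified 10-fold cross-validation.  Metrics: accuracy, sensitivity,
specificity, PPV, NPV (percent), AUC, F1 and the Matthews correlation
coefficient, with stratified nonparametric bootstrap 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "make_split",
    "kfold_plan",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_auc",
    "bootstrap_ci",
    "reconstruct_matrix_from_rates",
]

POSITIVE = "patient"  # positive class throughout


@dataclass
class SplitPlan:
    """Disjoint train/test id sets plus the rule that produced them."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_center: str
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class ConfusionMatrix:
    """2x2 table with `patient` as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def __str__(self) -> str:
        return (
            "              predicted\n"
            "              pat    ctl\n"
            f"true patient  {self.tp:4d}  {self.fn:4d}\n"
            f"true control  {self.fp:4d}  {self.tn:4d}"
        )


@dataclass
class MetricsReport:
    """All reported metrics; rates in percent, F1/MCC on their natural scale.

    ``ci`` maps metric name to a (lo, hi) 95% interval when computed.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    mcc: float
    auc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    protocol: str = ""

    def as_dict(self) -> dict:
        out = {
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            out["auc_pct"] = self.auc
        if self.ci:
            out["ci95"] = {k: list(v) for k, v in self.ci.items()}
        if self.protocol:
            out["protocol"] = self.protocol
        return out

    def __str__(self) -> str:
        rows = [
            f"accuracy    {self.accuracy:6.1f}%",
            f"sensitivity {self.sensitivity:6.1f}%",
            f"specificity {self.specificity:6.1f}%",
            f"PPV         {self.ppv:6.1f}%",
            f"NPV         {self.npv:6.1f}%",
            f"F1          {self.f1:7.2f}",
            f"MCC         {self.mcc:7.2f}",
        ]
        if self.auc is not None:
            rows.insert(1, f"AUC         {self.auc:6.1f}")
        return "\n".join(rows)


def make_split(
    cohort: pd.DataFrame,
    test_center: str = "D",
    test_fraction: float = 0.26,
    seed: int = 0,
) -> SplitPlan:
    """Center-aware train/test split.

    Every ear from ``test_center`` goes to the test set; the remainder of the
    test set (up to ``round(test_fraction * n)``) is drawn at random from the
    other centers.  Train and test are disjoint.
    """
    if test_center not in set(cohort["center"]):
        raise ValueError(f"test center {test_center!r} absent from cohort")
    n = len(cohort)
    n_test = int(round(test_fraction * n))
    d_ids = list(cohort.loc[cohort["center"] == test_center, "id"])
    if len(d_ids) > n_test:
        raise ValueError(
            f"center {test_center!r} alone ({len(d_ids)} ears) exceeds the requested "
            f"test size {n_test}"
        )
    rng = np.random.default_rng(seed)
    others = cohort.loc[cohort["center"] != test_center, "id"].to_numpy()
    extra = rng.choice(others, size=n_test - len(d_ids), replace=False)
    test_ids = tuple(d_ids) + tuple(extra)
    train_ids = tuple(i for i in cohort["id"] if i not in set(test_ids))
    return SplitPlan(train_ids, test_ids, test_center, test_fraction, seed)


def kfold_plan(
    cohort: pd.DataFrame, k: int = 10, seed: int = 0, stratified: bool = True
) -> list[tuple[tuple, tuple]]:
    """k-fold partition, stratified by class by default; returns
    (train_ids, test_ids) per fold.  When k exceeds the smaller class count
    (e.g. leave-one-out), stratification is impossible and the plan falls
    back to a plain shuffled partition.
    """
    n = len(cohort)
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    ids = cohort["id"].to_numpy()
    y = cohort["label"].to_numpy()
    if stratified and k <= min(np.bincount(pd.factorize(y)[0])):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (tuple(ids[tr]), tuple(ids[te]))
        for tr, te in splitter.split(np.zeros(n), y)
    ]


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Tabulate a confusion matrix from binary labels (1 = patient)."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning NaN", RuntimeWarning)
        return float("nan")
    return num / den


def compute_metrics(cm: ConfusionMatrix, protocol: str = "") -> MetricsReport:
    """Diagnostic metrics of a confusion matrix (rates in percent)."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warnings.warn("MCC: zero denominator, returning NaN", RuntimeWarning)
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        accuracy=100.0 * (tp + tn) / cm.n,
        sensitivity=100.0 * _safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=100.0 * _safe_ratio(tn, tn + fp, "specificity"),
        ppv=100.0 * _safe_ratio(tp, tp + fp, "PPV"),
        npv=100.0 * _safe_ratio(tn, tn + fn, "NPV"),
        f1=_safe_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        mcc=float(mcc),
        protocol=protocol,
    )


def roc_auc(labels: np.ndarray, class1_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney statistic with midrank tie handling)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(class1_scores, dtype=np.float64)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def bootstrap_ci(
    labels: np.ndarray,
    scores_or_preds: np.ndarray,
    metric,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bounds of ``metric(labels, values)`` over seeded
    stratified bootstrap resamples.  Degenerate resamples (metric NaN or
    raising) are skipped; their count is reported via a warning.
    """
    y = np.asarray(labels).astype(int)
    v = np.asarray(scores_or_preds)
    if y.size < 10:
        raise ValueError("bootstrap CI requires n >= 10")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    stats = []
    skipped = 0
    for _ in range(reps):
        idx = np.concatenate(
            [
                rng.choice(pos, size=pos.size, replace=True),
                rng.choice(neg, size=neg.size, replace=True),
            ]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = metric(y[idx], v[idx])
        except ValueError:
            skipped += 1
            continue
        if np.isnan(val):
            skipped += 1
            continue
        stats.append(val)
    if skipped:
        warnings.warn(f"bootstrap: skipped {skipped} degenerate resamples", RuntimeWarning)
    if not stats:
        raise ValueError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def reconstruct_matrix_from_rates(
    n_pos: int, n_neg: int, sens_pct: float, spec_pct: float
) -> ConfusionMatrix:
    """Nearest integer confusion matrix with the given printed rates.

    TP minimizes |TP/n_pos - sensitivity|, TN likewise; ties broken toward
    the larger count.
    """
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("rates must be in [0, 100]")

    def nearest(n: int, rate_pct: float) -> int:
        cand = np.arange(n + 1)
        err = np.abs(cand / max(n, 1) - rate_pct / 100.0)
        best = err.min()
        return int(cand[np.isclose(err, best)].max())  # tie -> larger count

    tp = nearest(n_pos, sens_pct)
    tn = nearest(n_neg, spec_pct)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
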