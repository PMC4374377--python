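"""ROC construction, optimal-cutoff selection and confusion-matrix
metrics with confidence intervals.

The two risk scores (logistic probability on [0, 1], ensemble vote score
on [0, 100]) are compared on the same footing: a full ROC curve, AUC with
a bootstrap CI, and — at the cutoff nearest the (0, 1) corner of ROC
space — sensitivity, specificity, PPV and NPV with Wald CIs, the interval
style the source report used (symmetric, clipped to [0, 1]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

__all__ = [
    "RocCurve",
    "PerformanceReport",
    "roc_curve",
    "auc_bootstrap_ci",
    "optimal_cutoff",
    "confusion_metrics",
    "score_histogram",
]


@dataclass
class RocCurve:
    """ROC points ordered from the all-negative to the all-positive
    operating point; one point per distinct threshold plus endpoints.
    ``thresholds[0]`` is +inf (call nothing positive)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None = None


def roc_curve(scores, labels) -> RocCurve:
    """Build the ROC curve; positive call convention is score >= cutoff.

    AUC is the trapezoidal area, which equals the Mann-Whitney
    probability that a random case outscores a random control, ties
    counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def auc_bootstrap_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                     seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (resampling patients).

    Resamples with a single-class draw are skipped (they carry no AUC).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(scores)
    aucs = []
    while len(aucs) < n_boot:
        idx = rng.integers(0, n, size=n)
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        aucs.append(skm.roc_auc_score(lb, scores[idx]))
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def optimal_cutoff(curve: RocCurve) -> float:
    """The threshold whose ROC point is nearest the upper-left corner,
    minimising sqrt((1-TPR)^2 + FPR^2).

    Ties are broken toward higher specificity (lower FPR), then toward
    the lower threshold value.
    """
    d = np.hypot(curve.fpr, 1.0 - curve.tpr)
    best = np.flatnonzero(d == d.min())
    # among equally near points prefer lowest FPR, then lowest threshold
    order = sorted(best, key=lambda i: (curve.fpr[i], curve.thresholds[i]))
    return float(curve.thresholds[order[0]])


def _wald_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    from scipy.stats import norm
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass
class PerformanceReport:
    """Operating-point metrics at a fixed cutoff, with 95% CIs.

    Proportions are on [0, 1]; a metric with a zero denominator is NaN
    and listed in ``not_evaluable``.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    not_evaluable: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv, "ppv_ci": list(self.ppv_ci),
            "npv": self.npv, "npv_ci": list(self.npv_ci),
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "not_evaluable": self.not_evaluable,
        }


def confusion_metrics(scores, labels, cutoff: float, n_boot: int = 2000,
                      seed: int | np.random.Generator = 0) -> PerformanceReport:
    """Confusion-matrix metrics at ``cutoff`` (positive call: score >=
    cutoff), Wald CIs for the proportions, bootstrap percentile CI for
    the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    calls = scores >= cutoff
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    tn = int(np.sum(~calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))

    nev: list[str] = []

    def ratio(k, n, name):
        if n == 0:
            nev.append(name)
            return np.nan
        return k / n

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    auc = roc_curve(scores, labels).auc
    auc_ci = auc_bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    return PerformanceReport(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        sensitivity_ci=_wald_ci(tp, tp + fn),
        specificity_ci=_wald_ci(tn, tn + fp),
        ppv_ci=_wald_ci(tp, tp + fp),
        npv_ci=_wald_ci(tn, tn + fn),
        auc=auc, auc_ci=auc_ci, not_evaluable=nev,
    )


def score_histogram(scores, labels, bin_width: float = 10.0,
                    lo: float = 0.0, hi: float | None = None) -> pd.DataFrame:
    """Per-class frequency table of the scores (the frequency-distribution
    view of the two methods). Bin counts sum to the class sizes; the top
    edge is inclusive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if hi is None:
        hi = max(scores.max(), lo + bin_width)
    nbins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    rows = {}
    for cls in (0, 1):
        counts, _ = np.histogram(scores[labels == cls], bins=edges)
        rows["controls" if cls == 0 else "cases"] = counts
    out = pd.DataFrame(rows, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
    # np.histogram makes the final bin closed on the right; keep its count
    return out


def report_to_json(report: PerformanceReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
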