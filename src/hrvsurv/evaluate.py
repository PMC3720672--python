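"""Diagnostic evaluation of the 7-day mortality prediction model.

ROC threshold sweep with trapezoid AUC (equivalent to the tie-corrected
pairwise concordance statistic), a DeLong-type 95% CI for the AUC, the
closest-to-top-left optimal operating point — the threshold minimising
sqrt((1 - sensitivity)^2 + (1 - specificity)^2) — and sensitivity /
specificity / PPV / NPV with Wilson-score confidence intervals.

Two classifiers of clinical interest are supported equally well: the fitted
probability of the final two-predictor logistic model (at most 4 distinct
risk values) and the single-cell rule "lnHFP < 2 AND ECOG 3-4".  Both are
just score vectors here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .exceptions import InputError

__all__ = [
    "ROCCurve",
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticSummary",
    "TopleftPoint",
    "roc_curve",
    "closest_topleft",
    "diagnostics",
    "predictive_values_from_prevalence",
]


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep: ``sensitivity[i]`` / ``specificity[i]`` are achieved
    by predicting positive when score >= ``thresholds[i]``.  Thresholds
    ascend, so sensitivity and (1 - specificity) are non-increasing."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]

    @property
    def vertices(self) -> np.ndarray:
        """(1 - specificity, sensitivity) pairs, one per threshold."""
        return np.column_stack([1.0 - self.specificity, self.sensitivity])


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC (Mann-Whitney with ties at 1/2) and its DeLong variance."""

    def midrank(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        n = x.size
        ranks = np.empty(n, dtype=float)
        i = 0
        while i < n:
            j = i
            while j < n and xs[j] == xs[i]:
                j += 1
            ranks[i:j] = 0.5 * (i + j - 1) + 1.0
            i = j
        out = np.empty(n, dtype=float)
        out[order] = ranks
        return out

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = midrank(np.concatenate([pos, neg]))
    pos_ranks = midrank(pos)
    neg_ranks = midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # structural components, events
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # structural components, non-events
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over all distinct score thresholds, trapezoid AUC, DeLong 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be aligned 1-D arrays")
    if np.unique(y).size < 2:
        raise InputError("AUC undefined: labels contain a single class")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    # sklearn returns thresholds descending with a leading +inf sentinel
    order = np.argsort(thr[1:], kind="mergesort")
    thresholds = thr[1:][order]
    sens = tpr[1:][order]
    spec = 1.0 - fpr[1:][order]
    auc, var = _delong_auc_variance(s, y)
    se = math.sqrt(var)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return ROCCurve(thresholds, sens, spec, auc, ci)


@dataclass(frozen=True)
class TopleftPoint:
    threshold: float
    sensitivity: float
    specificity: float
    distance: float


def closest_topleft(curve: ROCCurve) -> TopleftPoint:
    """Operating point minimising the Euclidean distance to (sens=1, spec=1);
    ties are broken toward the higher-specificity point."""
    if curve.thresholds.size == 0:
        raise InputError("empty ROC curve")
    d = np.hypot(1.0 - curve.sensitivity, 1.0 - curve.specificity)
    best = min(
        range(d.size),
        key=lambda i: (round(d[i], 15), -curve.specificity[i]),
    )
    return TopleftPoint(
        threshold=float(curve.thresholds[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        distance=float(d[best]),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise InputError(f"count {name}={v!r} must be a non-negative integer")

    @classmethod
    def from_scores(cls, scores, labels, threshold: float) -> "ConfusionCounts":
        """Classify positive when score >= threshold."""
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
        pred = s >= threshold
        return cls(
            tp=int((pred & (y == 1)).sum()),
            fn=int((~pred & (y == 1)).sum()),
            fp=int((pred & (y == 0)).sum()),
            tn=int((~pred & (y == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricEstimate:
    value: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate


def _proportion(k: int, n: int, ci_method: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan, math.nan, math.nan, False)
    lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    return MetricEstimate(k / n, float(lo), float(hi), True)


def diagnostics(counts: ConfusionCounts, ci_method: str = "wilson") -> DiagnosticSummary:
    """Sensitivity, specificity, PPV and NPV with 95% CIs.

    ``ci_method`` is 'wilson' (default) or 'beta' for the exact
    Clopper-Pearson interval.  A zero denominator flags that metric
    undefined rather than raising.
    """
    return DiagnosticSummary(
        sensitivity=_proportion(counts.tp, counts.tp + counts.fn, ci_method),
        specificity=_proportion(counts.tn, counts.tn + counts.fp, ci_method),
        ppv=_proportion(counts.tp, counts.tp + counts.fp, ci_method),
        npv=_proportion(counts.tn, counts.tn + counts.fn, ci_method),
    )


def predictive_values_from_prevalence(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV from test characteristics and prevalence (Bayes' rule).

    Degenerate denominators (e.g. a never-positive test) yield NaN for the
    affected value.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise InputError(f"{name}={v} outside [0, 1]")
    p = prevalence
    ppv_den = sensitivity * p + (1 - specificity) * (1 - p)
    npv_den = specificity * (1 - p) + (1 - sensitivity) * p
    ppv = sensitivity * p / ppv_den if ppv_den > 0 else math.nan
    npv = specificity * (1 - p) / npv_den if npv_den > 0 else math.nan
    return ppv, npv
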