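"""Classification statistics: ROC, AUC, Youden cut-off, exact intervals.

The area ratio of the positive class (non-treated patients, higher values)
is compared against the negative class with the empirical pair-counting
(Mann-Whitney) AUC, the Youden-index optimal cut-off over midpoint
thresholds, exact (Clopper-Pearson) binomial confidence intervals for
sensitivity and specificity, and the Hanley-McNeil standard-error interval
for the AUC.  Box-plot style five-number group summaries round out the
reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import beta, norm

__all__ = [
    "ROCResult",
    "empirical_auc",
    "roc_points",
    "youden_optimal_cutoff",
    "clopper_pearson",
    "auc_confidence_interval",
    "analyze_scores",
    "group_summary",
    "GroupStats",
]


@dataclass
class ROCResult:
    """Full ROC report for one positive/negative score split."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    positive_class: str = "nontreated"
    n_pos: int = 0
    n_neg: int = 0
    level: float = 0.95


def _as_arrays(pos: Sequence[float], neg: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    return pos, neg


def empirical_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Pair-counting (Mann-Whitney) AUC.

    (concordant pairs + half the tied pairs) / (n_pos * n_neg), where a
    pair is concordant when the positive-class value exceeds the
    negative-class value.
    """
    pos, neg = _as_arrays(pos, neg)
    diff = pos[:, None] - neg[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size)


def roc_points(
    pos: Sequence[float], neg: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sensitivity and specificity at midpoint thresholds.

    Candidate thresholds are the midpoints between adjacent distinct values
    of the pooled sample, extended by one threshold below and above all
    values so the ROC sweep reaches both corners.  Classification rule:
    positive when value > threshold.
    """
    pos, neg = _as_arrays(pos, neg)
    pooled = np.unique(np.concatenate([pos, neg]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return thresholds, sens, spec


def youden_optimal_cutoff(
    pos: Sequence[float], neg: Sequence[float]
) -> tuple[float, float, float, float]:
    """(cutoff, Youden J, sensitivity, specificity) maximizing sens+spec-1.

    Ties in J are broken toward the smallest maximizing threshold.
    """
    thresholds, sens, spec = roc_points(pos, neg)
    j = sens + spec - 1.0
    # ties (including 1-ulp float noise between count ratios that are
    # mathematically equal) break toward the smallest threshold
    best = int(np.argmax(j >= j.max() - 1e-12))
    return float(thresholds[best]), float(j[best]), float(sens[best]), float(spec[best])


def clopper_pearson(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles.

    lo = Beta(alpha/2; k, n-k+1), hi = Beta(1-alpha/2; k+1, n-k), with
    lo = 0 at k = 0 and hi = 1 at k = n.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def auc_confidence_interval(
    pos: Sequence[float],
    neg: Sequence[float],
    auc: float | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Hanley-McNeil standard-error interval for the AUC, clipped to [0, 1].

    With a degenerate AUC (0 or 1) at small n the standard error vanishes;
    the clipped interval is still returned, with a warning.
    """
    pos, neg = _as_arrays(pos, neg)
    a = empirical_auc(pos, neg) if auc is None else float(auc)
    n_pos, n_neg = pos.size, neg.size
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    if a in (0.0, 1.0):
        warnings.warn(
            "degenerate AUC; Hanley-McNeil interval collapses and is only clipped",
            stacklevel=2,
        )
    z = float(norm.ppf(0.5 + level / 2.0))
    return max(a - z * se, 0.0), min(a + z * se, 1.0)


def analyze_scores(
    pos: Sequence[float],
    neg: Sequence[float],
    positive_class: str = "nontreated",
    level: float = 0.95,
) -> ROCResult:
    """Complete ROC report for positive vs negative scores."""
    pos, neg = _as_arrays(pos, neg)
    thresholds, sens, spec = roc_points(pos, neg)
    auc = empirical_auc(pos, neg)
    cutoff, j, sens_c, spec_c = youden_optimal_cutoff(pos, neg)
    tp = int(round(sens_c * pos.size))
    tn = int(round(spec_c * neg.size))
    return ROCResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        auc_ci=auc_confidence_interval(pos, neg, auc, level),
        youden=j,
        cutoff=cutoff,
        sens_at_cutoff=sens_c,
        spec_at_cutoff=spec_c,
        sens_ci=clopper_pearson(tp, pos.size, level),
        spec_ci=clopper_pearson(tn, neg.size, level),
        positive_class=positive_class,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        level=level,
    )


@dataclass
class GroupStats:
    """Box-plot five-number summary with 1.5 IQR whiskers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)
    minimum: float = float("nan")
    maximum: float = float("nan")


def group_summary(values: Sequence[float]) -> GroupStats:
    """Quartiles (linear interpolation), whiskers at Q1/Q3 -/+ 1.5 IQR, and
    the observations outside the whiskers flagged as outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return GroupStats(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in outliers),
        minimum=float(v.min()),
        maximum=float(v.max()),
    )
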