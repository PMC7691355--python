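"""ROC curves from grouped operating points, trapezoidal AUC, and Hanley
standard errors / AUC comparisons.

With only stratum-level counts the ROC curve is a polygon through the
operating points (1 - specificity, sensitivity) anchored at (0,0) and (1,1),
and its area is the trapezoidal sum.  Standard errors follow Hanley &
McNeil's closed form based on the Wilcoxon interpretation of the AUC,

    SE^2 = [A(1-A) + (n_c - 1)(Q1 - A^2) + (n_n - 1)(Q2 - A^2)] / (n_c n_n),
    Q1 = A / (2 - A),   Q2 = 2 A^2 / (1 + A),

with ``n_c`` cases and ``n_n`` non-cases; the difference between two AUCs is
tested with a normal z using SE_diff = sqrt(se1^2 + se2^2 - 2 r se1 se2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .correction import OperatingPoint

__all__ = [
    "ROCCurve",
    "AUCEstimate",
    "AUCDifference",
    "build_roc",
    "auc_trapezoid",
    "hanley_se",
    "auc_ci",
    "auc_difference_test",
    "plot_roc",
]


@dataclass(frozen=True)
class ROCCurve:
    """Anchored, monotone polygon through grouped operating points.

    ``n_cases``/``n_noncases`` are the disease margins backing the curve;
    for a corrected curve they are real-valued (observed cases plus the
    expected latent PCDP mass, and the correspondingly shrunk non-cases).
    """

    points: tuple[tuple[float, float], ...]  # (fpr, tpr), sorted by fpr
    variant: str
    n_cases: float
    n_noncases: float


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    level: float


@dataclass(frozen=True)
class AUCDifference:
    difference: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    degenerate: bool  # True when se_diff == 0 forced the verdict


def build_roc(points: Sequence[OperatingPoint]) -> ROCCurve:
    """Assemble an ROC curve from operating points of a single variant.

    Converts percent metrics to (fpr, tpr) = (1 - spec/100, sens/100),
    appends the (0,0) and (1,1) anchors, sorts by fpr and rejects any
    decrease in tpr along the curve (a staircase violation means the
    operating points cannot come from one monotone test).  The disease
    margins are taken from the highest cutoff, where (for a corrected
    variant) every corrected stratum lies below the cutoff and the case
    margin includes the full expected-PCDP mass.
    """
    if not points:
        raise ValueError("need at least one operating point")
    variants = {p.variant for p in points}
    if len(variants) > 1:
        raise ValueError(f"mixed variants in one curve: {sorted(variants)}")
    top = max(points, key=lambda p: p.cutoff)
    xy = sorted(
        {(1.0 - p.specificity / 100.0, p.sensitivity / 100.0, p.cutoff)
         for p in points},
        key=lambda t: (t[0], t[1]),
    )
    bad = [
        (a[2], b[2])
        for a, b in zip(xy, xy[1:])
        if b[1] < a[1] - 1e-12
    ]
    if bad:
        raise ValueError(
            "operating points are not ROC-monotone; offending cutoff pairs "
            f"(by increasing fpr): {bad}"
        )
    pts = [(0.0, 0.0)] + [(x, y) for x, y, _ in xy] + [(1.0, 1.0)]
    # drop duplicate anchors if an operating point already sits on them
    dedup: list[tuple[float, float]] = []
    for p in pts:
        if not dedup or p != dedup[-1]:
            dedup.append(p)
    return ROCCurve(
        points=tuple(dedup),
        variant=points[0].variant,
        n_cases=top.tp + top.fn,
        n_noncases=top.fp + top.tn,
    )


def auc_trapezoid(curve: ROCCurve) -> float:
    """Area under the polygonal curve by the trapezoidal rule."""
    fpr = np.array([p[0] for p in curve.points])
    tpr = np.array([p[1] for p in curve.points])
    return float(np.trapezoid(tpr, fpr))


def hanley_se(auc: float, n_cases: float, n_noncases: float) -> float:
    """Hanley-McNeil standard error of a Wilcoxon AUC."""
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    if n_cases < 1 or n_noncases < 1:
        raise ValueError("need at least one case and one non-case")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_cases - 1.0) * (q1 - a * a)
        + (n_noncases - 1.0) * (q2 - a * a)
    ) / (n_cases * n_noncases)
    # var can round to a tiny negative at a = 1
    return math.sqrt(max(var, 0.0))


def auc_ci(
    auc: float, n_cases: float, n_noncases: float, level: float = 0.95
) -> AUCEstimate:
    """Wald confidence interval for the AUC, truncated to [0, 1]."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    se = hanley_se(auc, n_cases, n_noncases)
    z = norm.ppf(0.5 + level / 2.0)
    return AUCEstimate(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        level=level,
    )


def auc_difference_test(
    a1: AUCEstimate, a2: AUCEstimate, r: float = 0.0, level: float = 0.95
) -> AUCDifference:
    """Normal-theory test of AUC1 - AUC2.

    ``r`` is the correlation between the two AUC estimates (0 for
    independent curves; supply the correlated-curve value when both curves
    come from the same subjects).
    """
    if not (-1.0 <= r <= 1.0):
        raise ValueError(f"r must be in [-1, 1], got {r}")
    diff = a1.auc - a2.auc
    se_diff = math.sqrt(max(a1.se**2 + a2.se**2 - 2.0 * r * a1.se * a2.se, 0.0))
    zq = norm.ppf(0.5 + level / 2.0)
    if se_diff == 0.0:
        if diff == 0.0:
            return AUCDifference(0.0, 0.0, 0.0, 0.0, 1.0, degenerate=False)
        return AUCDifference(
            diff, diff, diff, math.inf if diff > 0 else -math.inf, 0.0,
            degenerate=True,
        )
    z = diff / se_diff
    p = 2.0 * norm.sf(abs(z))
    if diff == 0.0:
        p = 1.0
    return AUCDifference(
        difference=diff,
        ci_low=diff - zq * se_diff,
        ci_high=diff + zq * se_diff,
        z=z,
        p=p,
        degenerate=False,
    )


def plot_roc(curves: Sequence[ROCCurve], path: str) -> None:
    """Overlay ROC polygons and save to ``path`` (format from extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for curve in curves:
        fpr = [p[0] for p in curve.points]
        tpr = [p[1] for p in curve.points]
        auc = auc_trapezoid(curve)
        ax.plot(fpr, tpr, marker="o", label=f"{curve.variant} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
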