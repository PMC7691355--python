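"""Uncorrected and sojourn-time-corrected classification metrics.

In population-based screening, a "case" is a screen-detected cancer or an
interval cancer surfacing before the next scheduled screen; everyone else is
treated as disease-free.  That convention undercounts disease: cancers in
the pre-clinical detectable phase (PCDP) among screen-negatives are neither
detected nor given time to surface, so naive sensitivity is inflated.

The correction estimates, for each biomarker stratum below the referral
threshold, the expected number of latent PCDP cases (``n * lambda1 * MST``)
and moves that mass from the true negatives to the false negatives before
computing metrics.  Because the shift happens entirely within the
test-negative margin, PPV is unchanged while sensitivity, specificity and
NPV all drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .markov import SojournModel, expected_pcdp_cases, invert_lambda1

__all__ = [
    "PSAStratum",
    "ScreeningTable",
    "PCDPEstimate",
    "OperatingPoint",
    "contingency_at_cutoff",
    "uncorrected_metrics",
    "estimate_pcdp_by_stratum",
    "pooled_pcdp",
    "corrected_metrics",
    "metrics_table",
]

_BOUNDARY_ATOL = 1e-9


@dataclass(frozen=True)
class PSAStratum:
    """One biomarker interval [psa_low, psa_high) with its first-round counts."""

    psa_low: float
    psa_high: float  # math.inf for the terminal stratum
    n_participants: int
    screen_detected: int
    interval_cancers: int

    def __post_init__(self) -> None:
        if not self.psa_low < self.psa_high:
            raise ValueError(
                f"stratum bounds must satisfy psa_low < psa_high, got "
                f"[{self.psa_low}, {self.psa_high})"
            )
        for name in ("n_participants", "screen_detected", "interval_cancers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.screen_detected + self.interval_cancers > self.n_participants:
            raise ValueError(
                f"cases ({self.screen_detected}+{self.interval_cancers}) exceed "
                f"participants ({self.n_participants}) in stratum "
                f"[{self.psa_low}, {self.psa_high})"
            )

    @property
    def cases(self) -> int:
        return self.screen_detected + self.interval_cancers


@dataclass(frozen=True)
class ScreeningTable:
    """Ordered, contiguous biomarker strata plus the inter-screen interval."""

    strata: tuple[PSAStratum, ...]
    interval_years: float

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("ScreeningTable needs at least one stratum")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")
        if abs(self.strata[0].psa_low) > _BOUNDARY_ATOL:
            raise ValueError("strata must start at 0")
        for a, b in zip(self.strata, self.strata[1:]):
            if abs(a.psa_high - b.psa_low) > _BOUNDARY_ATOL:
                raise ValueError(
                    f"strata not contiguous: [{a.psa_low}, {a.psa_high}) then "
                    f"[{b.psa_low}, {b.psa_high})"
                )
        if not math.isinf(self.strata[-1].psa_high):
            raise ValueError("last stratum must extend to infinity")

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Valid cutoff values: the lower bound of every stratum."""
        return tuple(s.psa_low for s in self.strata)

    @property
    def n_total(self) -> int:
        return sum(s.n_participants for s in self.strata)

    @property
    def total_cases(self) -> int:
        return sum(s.cases for s in self.strata)


@dataclass(frozen=True)
class PCDPEstimate:
    """Per-stratum pre-clinical incidence and expected latent cases."""

    stratum: PSAStratum
    lambda1: float
    p_pcdp: float
    expected_cases: float

    @property
    def p_ic(self) -> float:
        return self.stratum.interval_cancers / self.stratum.n_participants


@dataclass(frozen=True)
class OperatingPoint:
    """Contingency counts and derived metrics at one cutoff.

    For the corrected variant, ``fn`` and ``tn`` are real-valued: the
    expected latent PCDP mass below the cutoff has been moved from the true
    negatives into the false negatives.
    """

    cutoff: float
    variant: str  # "uncorrected" | "corrected"
    tp: float
    fn: float
    fp: float
    tn: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float

    @classmethod
    def from_counts(
        cls, cutoff: float, variant: str, tp: float, fn: float, fp: float, tn: float
    ) -> "OperatingPoint":
        if min(tp, fn, fp, tn) < 0:
            raise ValueError("contingency counts must be >= 0")
        if tp + fn <= 0 or fp + tn <= 0:
            raise ValueError(
                f"empty disease margin at cutoff {cutoff}: "
                f"cases={tp + fn}, non-cases={fp + tn}"
            )
        if tp + fp <= 0 or tn + fn <= 0:
            raise ValueError(
                f"empty test margin at cutoff {cutoff}: "
                f"positives={tp + fp}, negatives={tn + fn}"
            )
        sens = 100.0 * tp / (tp + fn)
        spec = 100.0 * tn / (tn + fp)
        return cls(
            cutoff=cutoff,
            variant=variant,
            tp=tp,
            fn=fn,
            fp=fp,
            tn=tn,
            sensitivity=sens,
            specificity=spec,
            ppv=100.0 * tp / (tp + fp),
            npv=100.0 * tn / (tn + fn),
            youden=sens + spec - 100.0,
        )


def _cutoff_index(table: ScreeningTable, cutoff: float) -> int:
    """Index of the first stratum at/above ``cutoff``; error off-boundary."""
    bounds = table.boundaries
    for i, b in enumerate(bounds):
        if abs(b - cutoff) <= _BOUNDARY_ATOL:
            return i
    below = max((b for b in bounds if b < cutoff), default=None)
    above = min((b for b in bounds if b > cutoff), default=None)
    raise ValueError(
        f"cutoff {cutoff} is not a stratum boundary of this table; grouped "
        f"counts cannot resolve it (nearest boundaries: {below} and {above})"
    )


def contingency_at_cutoff(
    table: ScreeningTable, cutoff: float
) -> tuple[int, int, int, int]:
    """(tp, fn, fp, tn) treating PSA >= cutoff as test-positive.

    Cases (screen-detected + interval cancers) in strata at/above the cutoff
    are true positives; cases below are false negatives; non-cases split
    likewise into false positives and true negatives.
    """
    i = _cutoff_index(table, cutoff)
    tp = sum(s.cases for s in table.strata[i:])
    fn = sum(s.cases for s in table.strata[:i])
    fp = sum(s.n_participants - s.cases for s in table.strata[i:])
    tn = sum(s.n_participants - s.cases for s in table.strata[:i])
    return tp, fn, fp, tn


def uncorrected_metrics(table: ScreeningTable, cutoff: float) -> OperatingPoint:
    """Naive metrics: interval cancers are the only false negatives."""
    tp, fn, fp, tn = contingency_at_cutoff(table, cutoff)
    return OperatingPoint.from_counts(cutoff, "uncorrected", tp, fn, fp, tn)


Lambda1Source = Union[str, Sequence[float]]


def estimate_pcdp_by_stratum(
    table: ScreeningTable,
    mst: float,
    lambda1_source: Lambda1Source = "invert-exact",
    referral_threshold: float = 4.0,
) -> list[PCDPEstimate]:
    """Estimate latent PCDP cases for every stratum below the referral
    threshold.

    Each stratum's interval-cancer proportion ``p_ic = IC / n`` is converted
    to a pre-clinical incidence rate ``lambda1`` (by exact or linearised
    inversion of the three-state model, or taken from a supplied list, e.g.
    externally published estimates), then to the equilibrium PCDP prevalence
    ``lambda1 * mst`` and the unrounded expected case count ``n * lambda1 *
    mst``.

    Parameters
    ----------
    lambda1_source : "invert-exact" | "invert-linear" | sequence of float
        A supplied sequence must have one rate per sub-threshold stratum, in
        stratum order.
    """
    strata = [
        s for s in table.strata if s.psa_high <= referral_threshold + _BOUNDARY_ATOL
    ]
    supplied: Sequence[float] | None = None
    if not isinstance(lambda1_source, str):
        supplied = list(lambda1_source)
        if len(supplied) != len(strata):
            raise ValueError(
                f"supplied lambda1 list has length {len(supplied)}, expected "
                f"{len(strata)} (one per stratum below {referral_threshold})"
            )
    elif lambda1_source not in ("invert-exact", "invert-linear"):
        raise ValueError(f"unknown lambda1_source {lambda1_source!r}")

    out: list[PCDPEstimate] = []
    for j, s in enumerate(strata):
        if s.n_participants == 0:
            raise ValueError(
                f"stratum [{s.psa_low}, {s.psa_high}) has zero participants"
            )
        if supplied is not None:
            lam1 = float(supplied[j])
        else:
            p_ic = s.interval_cancers / s.n_participants
            method = "exact" if lambda1_source == "invert-exact" else "linear"
            lam1 = invert_lambda1(p_ic, mst, table.interval_years, method=method)
        model = SojournModel(lam1, mst)
        p_pcdp = lam1 * mst
        out.append(
            PCDPEstimate(
                stratum=s,
                lambda1=lam1,
                p_pcdp=p_pcdp,
                expected_cases=expected_pcdp_cases(s.n_participants, model),
            )
        )
    return out


def pooled_pcdp(
    table: ScreeningTable,
    mst: float,
    lambda1: float | None = None,
    referral_threshold: float = 4.0,
) -> PCDPEstimate:
    """PCDP estimate for all sub-threshold strata pooled into one.

    With ``lambda1=None`` the pooled interval-cancer proportion is inverted
    exactly; a supplied ``lambda1`` (e.g. a published pooled rate) is used
    as-is.  Note the pooled expected count is an independent aggregate and
    generally differs from the sum of the stratum-wise expected counts,
    because inversion is non-linear and rates are heterogeneous.
    """
    strata = [
        s for s in table.strata if s.psa_high <= referral_threshold + _BOUNDARY_ATOL
    ]
    n = sum(s.n_participants for s in strata)
    ic = sum(s.interval_cancers for s in strata)
    sd = sum(s.screen_detected for s in strata)
    pooled = PSAStratum(0.0, referral_threshold, n, sd, ic)
    if lambda1 is None:
        lambda1 = invert_lambda1(ic / n, mst, table.interval_years, method="exact")
    model = SojournModel(lambda1, mst)
    return PCDPEstimate(
        stratum=pooled,
        lambda1=lambda1,
        p_pcdp=lambda1 * mst,
        expected_cases=expected_pcdp_cases(n, model),
    )


def corrected_metrics(
    table: ScreeningTable, cutoff: float, pcdp: Iterable[PCDPEstimate]
) -> OperatingPoint:
    """Sojourn-time-corrected metrics at one cutoff.

    The unrounded expected PCDP counts of strata entirely below the cutoff
    are added to the false negatives and subtracted from the true negatives:
    those latent cases currently sit, unlabelled, among the test-negative
    "disease-free".  PPV is untouched (the positive margin is not involved)
    and the test-negative margin is conserved.
    """
    tp, fn, fp, tn = contingency_at_cutoff(table, cutoff)
    x = sum(
        e.expected_cases
        for e in pcdp
        if e.stratum.psa_high <= cutoff + _BOUNDARY_ATOL
    )
    if x > tn:
        raise ValueError(
            f"expected PCDP mass below cutoff {cutoff} ({x:.1f}) exceeds the "
            f"true negatives ({tn}); correction not applicable"
        )
    return OperatingPoint.from_counts(cutoff, "corrected", tp, fn + x, fp, tn - x)


def metrics_table(
    table: ScreeningTable,
    cutoffs: Sequence[float],
    mst: float,
    lambda1_source: Lambda1Source = "invert-exact",
    referral_threshold: float = 4.0,
) -> list[OperatingPoint]:
    """Uncorrected and corrected operating points at each cutoff,
    deterministically ordered by (cutoff, variant)."""
    if not cutoffs:
        return []
    pcdp = estimate_pcdp_by_stratum(table, mst, lambda1_source, referral_threshold)
    points: list[OperatingPoint] = []
    for c in cutoffs:
        points.append(uncorrected_metrics(table, c))
        points.append(corrected_metrics(table, c, pcdp))
    points.sort(key=lambda p: (p.cutoff, p.variant))
    return points
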