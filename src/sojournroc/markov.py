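"""Three-state progressive disease model with exponential dwell times.

The natural history of a screen-detectable cancer is described by three
states: state 0, free of detectable disease; state 1, the pre-clinical
detectable phase (PCDP), in which the tumour is asymptomatic but would be
found by the screening test; and state 2, the clinical phase (CP), in which
the disease surfaces with symptoms.  Transitions are progressive
(0 -> 1 -> 2) with constant intensities: ``lambda1``, the pre-clinical
incidence rate (per person-year), and ``lambda2 = 1/MST``, the reciprocal of
the mean sojourn time in the PCDP.

With both dwell times exponential the time-homogeneous chain has the closed
form, starting from state 0,

    p00(t) = exp(-lambda1 * t)
    p01(t) = lambda1/(lambda2 - lambda1) * (exp(-lambda1*t) - exp(-lambda2*t))
    p02(t) = 1 - p00(t) - p01(t)

``p02(delta)`` is the probability that a person disease-free at a negative
screen surfaces clinically within the inter-screen interval ``delta`` — the
model's interval-cancer probability.  Inverting that relationship on an
observed interval-cancer proportion recovers ``lambda1`` for a biomarker
stratum, which in turn yields the expected number of latent PCDP cases among
screen-negatives (the quantity used to correct sensitivity and specificity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

from scipy.optimize import brentq

__all__ = [
    "SojournModel",
    "StateProbabilities",
    "transition_probabilities",
    "interval_cancer_prob",
    "invert_lambda1",
    "pcdp_prevalence",
    "expected_pcdp_cases",
]

#: Relative closeness of lambda1 to lambda2 below which the equal-rates
#: analytic limit p01 = lambda1 * t * exp(-lambda1 * t) is used, avoiding
#: catastrophic cancellation in the two-rate closed form.
EQUAL_RATE_RTOL = 1e-9


@dataclass(frozen=True)
class SojournModel:
    """Transition rates of the progressive three-state model.

    Parameters
    ----------
    lambda1 : float
        Pre-clinical incidence rate (state 0 -> 1), per person-year, >= 0.
    mst : float
        Mean sojourn time in the PCDP, years, > 0.  The progression rate
        (state 1 -> 2) is ``lambda2 = 1/mst``.
    """

    lambda1: float
    mst: float

    def __post_init__(self) -> None:
        if not (self.lambda1 >= 0.0):
            raise ValueError(f"lambda1 must be >= 0, got {self.lambda1}")
        if not (self.mst > 0.0):
            raise ValueError(f"mst must be > 0, got {self.mst}")

    @property
    def lambda2(self) -> float:
        """Progression rate PCDP -> clinical phase, per person-year."""
        return 1.0 / self.mst


@dataclass(frozen=True)
class StateProbabilities:
    """Occupancy probabilities of states 0/1/2 at a given elapsed time."""

    p00: float
    p01: float
    p02: float


def transition_probabilities(model: SojournModel, t: float) -> StateProbabilities:
    """State occupancy at time ``t`` for a person in state 0 at time 0.

    Uses the two-rate closed form, switching to the analytic equal-rates
    limit when ``lambda1`` is within :data:`EQUAL_RATE_RTOL` of ``lambda2``.

    Parameters
    ----------
    model : SojournModel
    t : float
        Elapsed time in years, >= 0.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    l1 = model.lambda1
    l2 = model.lambda2
    p00 = math.exp(-l1 * t)
    if abs(l1 - l2) < EQUAL_RATE_RTOL * l2:
        p01 = l1 * t * math.exp(-l1 * t)
    else:
        p01 = l1 / (l2 - l1) * (math.exp(-l1 * t) - math.exp(-l2 * t))
    p02 = 1.0 - p00 - p01
    # guard against -1e-17 style round-off at t ~ 0
    if p02 < 0.0:
        p02 = 0.0
    return StateProbabilities(p00=p00, p01=p01, p02=p02)


def interval_cancer_prob(model: SojournModel, delta: float) -> float:
    """Probability of surfacing clinically within ``delta`` years of a
    negative screen, for a person free of detectable disease at the screen.

    This equals ``p02(delta)`` of :func:`transition_probabilities`: the
    person must enter the PCDP *and* progress to the clinical phase before
    the next scheduled screen.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    return transition_probabilities(model, delta).p02


def invert_lambda1(
    p_ic: float,
    mst: float,
    delta: float,
    method: Literal["exact", "linear"] = "exact",
) -> float:
    """Recover the pre-clinical incidence rate from an interval-cancer
    probability.

    Parameters
    ----------
    p_ic : float
        Observed probability of an interval cancer within ``delta`` years of
        a negative screen, in [0, 1).
    mst : float
        Mean sojourn time in years.
    delta : float
        Inter-screen interval in years.
    method : {"exact", "linear"}
        ``"exact"`` solves ``p02(delta; lambda1, mst) = p_ic`` for lambda1 by
        bracketed root finding (residual <= 1e-12).  ``"linear"`` uses the
        small-rate linearisation

            lambda1 = p_ic / (delta - mst * (1 - exp(-delta/mst)))

        which is the leading-order expansion of the exact relation in
        lambda1 and agrees with it to O(lambda1^2 * delta^2).

    Raises
    ------
    ValueError
        If ``p_ic`` is outside [0, 1) or exceeds the model's attainable
        interval-cancer probability ``1 - exp(-delta/mst)`` (no rate, however
        large, can produce it), or if the root finder fails to converge.
    """
    if not (0.0 <= p_ic < 1.0):
        raise ValueError(f"p_ic must be in [0, 1), got {p_ic}")
    if mst <= 0 or delta <= 0:
        raise ValueError("mst and delta must be > 0")
    if p_ic == 0.0:
        return 0.0

    if method == "linear":
        return p_ic / (delta - mst * (1.0 - math.exp(-delta / mst)))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    # As lambda1 -> inf, p02(delta) -> 1 - exp(-delta/mst): solvability bound.
    p_sup = 1.0 - math.exp(-delta / mst)
    if p_ic >= p_sup:
        raise ValueError(
            f"p_ic={p_ic:.6g} is not attainable: the model's interval-cancer "
            f"probability is bounded by 1 - exp(-delta/mst) = {p_sup:.6g} "
            f"for mst={mst}, delta={delta}"
        )

    def residual(l1: float) -> float:
        return interval_cancer_prob(SojournModel(l1, mst), delta) - p_ic

    lo, hi = 0.0, 10.0 / delta
    n_expand = 0
    while residual(hi) < 0.0:
        hi *= 2.0
        n_expand += 1
        if n_expand > 200:
            raise ValueError("invert_lambda1 failed to bracket a root")
    root = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(residual(root)) > 1e-12:
        raise ValueError(
            f"invert_lambda1 did not converge: residual {residual(root):.3g}"
        )
    return float(root)


def pcdp_prevalence(
    model: SojournModel, horizon: Union[float, Literal["equilibrium"]]
) -> float:
    """Probability of occupying the PCDP.

    ``horizon="equilibrium"`` returns the quasi-stationary value
    ``lambda1 * mst`` (flow balance between onset and progression), valid in
    the screening regime ``lambda1 * mst << 1``; a numeric horizon returns
    the finite-time occupancy ``p01(horizon)``, offered for sensitivity
    analysis.
    """
    if horizon == "equilibrium":
        if model.lambda1 * model.mst >= 1.0:
            raise ValueError(
                f"equilibrium approximation invalid: lambda1*mst = "
                f"{model.lambda1 * model.mst:.3g} >= 1"
            )
        return model.lambda1 * model.mst
    return transition_probabilities(model, float(horizon)).p01


def expected_pcdp_cases(n: float, model: SojournModel) -> float:
    """Expected number of latent PCDP cases among ``n`` screenees.

    Returns ``n * lambda1 * mst`` as an unrounded real number; rounding for
    display is a presentation concern and is never applied here, because the
    corrected sensitivity/specificity formulas consume the exact value.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return n * pcdp_prevalence(model, "equilibrium")
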