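"""Synthetic screening cohorts under the three-state progressive model.

Each simulated person belongs to a fixed biomarker stratum with its own
pre-clinical incidence rate.  Disease onset follows an exponential clock
running from the start of a pre-screen run-in period; the sojourn in the
pre-clinical detectable phase (PCDP) is exponential with mean MST.  At the
screen (end of run-in) a person is either disease-free (state 0) or in the
PCDP (state 1); people whose disease already surfaced clinically before the
screen do not attend and are excluded from the cohort.  Clinical surfacing
within the inter-screen interval produces an interval cancer.

The simulator closes the loop on the estimation pipeline: summarising a
cohort to stratum counts and feeding it to the correction module should
recover the generating rates and the true latent-PCDP burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .correction import PSAStratum, ScreeningTable

__all__ = ["SimulationParams", "PersonRecord", "simulate_cohort", "summarize_to_table"]


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters for a synthetic screening cohort.

    Parameters
    ----------
    strata_bounds : sequence of (low, high)
        Contiguous biomarker intervals starting at 0, last high = inf.
    n_per_stratum : sequence of int
        Cohort size entering the run-in, per stratum.
    lambda1_per_stratum : sequence of float
        Pre-clinical incidence rate (per person-year), per stratum.
    mst : float
        Mean sojourn time in years.
    interval_years : float
        Inter-screen interval (interval-cancer observation window).
    run_in_years : float
        Pre-screen history establishing PCDP prevalence at the screen; 40
        years by default, long enough that the prevalence among attenders is
        at its quasi-equilibrium to well under 1% relative error at
        screening-scale rates.
    seed : int
        Root seed; per-stratum streams are spawned from it so results are
        reproducible under stratum reordering.
    """

    strata_bounds: tuple[tuple[float, float], ...]
    n_per_stratum: tuple[int, ...]
    lambda1_per_stratum: tuple[float, ...]
    mst: float = 6.75
    interval_years: float = 4.0
    run_in_years: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.strata_bounds)
        if len(self.n_per_stratum) != k or len(self.lambda1_per_stratum) != k:
            raise ValueError("per-stratum sequences must have equal length")
        if any(n < 0 for n in self.n_per_stratum):
            raise ValueError("n_per_stratum must be >= 0")
        if any(l1 < 0 for l1 in self.lambda1_per_stratum):
            raise ValueError("lambda1_per_stratum must be >= 0")
        if self.mst <= 0 or self.interval_years <= 0 or self.run_in_years < 0:
            raise ValueError("mst, interval_years > 0 and run_in_years >= 0 required")


@dataclass(frozen=True)
class PersonRecord:
    """One screen attender; times are measured from the screen in years.

    ``onset_time`` is negative for onset during the run-in, ``None`` when no
    onset occurred by the end of the interval-cancer window.
    ``clinical_time`` is ``None`` when surfacing falls beyond that window.
    """

    stratum: int
    state_at_screen: int  # 0 = disease-free, 1 = PCDP
    onset_time: Optional[float]
    clinical_time: Optional[float]
    interval_cancer: bool


def _simulate_stratum(
    rng: np.random.Generator, n: int, lambda1: float, params: SimulationParams
) -> dict[str, np.ndarray]:
    """Vectorised event times for one stratum; screen attenders only."""
    t_screen = params.run_in_years
    horizon = t_screen + params.interval_years
    if lambda1 > 0.0:
        onset = rng.exponential(1.0 / lambda1, size=n)
    else:
        onset = np.full(n, np.inf)
    sojourn = rng.exponential(params.mst, size=n)
    clinical = onset + sojourn
    attends = clinical > t_screen  # surfaced-before-screen cases never attend
    onset = onset[attends]
    clinical = clinical[attends]
    in_pcdp = onset < t_screen
    ic = clinical <= horizon
    return {
        "onset": onset - t_screen,
        "clinical": clinical - t_screen,
        "state": in_pcdp.astype(np.int8),
        "interval_cancer": ic,
    }


def _stratum_arrays(params: SimulationParams) -> list[dict[str, np.ndarray]]:
    streams = np.random.SeedSequence(params.seed).spawn(len(params.strata_bounds))
    return [
        _simulate_stratum(np.random.default_rng(ss), n, l1, params)
        for ss, n, l1 in zip(streams, params.n_per_stratum, params.lambda1_per_stratum)
    ]


def simulate_cohort(params: SimulationParams) -> list[PersonRecord]:
    """Simulate one screening round; returns the screen attenders."""
    records: list[PersonRecord] = []
    for k, arr in enumerate(_stratum_arrays(params)):
        for onset, clinical, state, ic in zip(
            arr["onset"], arr["clinical"], arr["state"], arr["interval_cancer"]
        ):
            observed = onset <= params.interval_years
            records.append(
                PersonRecord(
                    stratum=k,
                    state_at_screen=int(state),
                    onset_time=float(onset) if observed else None,
                    clinical_time=(
                        float(clinical)
                        if clinical <= params.interval_years
                        else None
                    ),
                    interval_cancer=bool(ic),
                )
            )
    return records


def summarize_to_table(
    records: Sequence[PersonRecord],
    params: SimulationParams,
    detection_threshold: float = 4.0,
) -> tuple[ScreeningTable, list[int]]:
    """Collapse person records to stratum counts plus the latent truth.

    Strata at/above ``detection_threshold`` report their PCDP occupants as
    screen-detected cancers; below it the test cannot flag them, so
    ``screen_detected`` is 0 and the occupancy is returned separately as
    ``true_pcdp_counts`` (the ground truth the correction estimates).
    Interval cancers are counted among persons disease-free at the screen —
    the estimand targeted by the rate inversion; sub-threshold PCDP
    occupants who surface during the interval are part of the latent truth,
    not of the interval-cancer count.
    """
    k = len(params.strata_bounds)
    n = [0] * k
    sd = [0] * k
    ic = [0] * k
    true_pcdp = [0] * k
    detectable = [low >= detection_threshold for low, _ in params.strata_bounds]
    for r in records:
        n[r.stratum] += 1
        if r.state_at_screen == 1:
            true_pcdp[r.stratum] += 1
            if detectable[r.stratum]:
                sd[r.stratum] += 1
        elif r.interval_cancer:
            ic[r.stratum] += 1
    strata = tuple(
        PSAStratum(low, high, n[j], sd[j], ic[j])
        for j, (low, high) in enumerate(params.strata_bounds)
    )
    return ScreeningTable(strata, params.interval_years), true_pcdp
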