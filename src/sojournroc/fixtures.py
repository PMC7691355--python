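"""Packaged first-round data of the Finnish PSA screening trial.

The trial screened men aged 55-67 with a 4-year inter-screen interval;
20,687 evaluable participants yielded 584 screen-detected and 129 interval
cancers.  Published per-stratum pre-clinical incidence rates (lambda1) and
the published table cells reproduced by the ``reproduce`` command are kept
here, each annotated with its provenance (published vs derived).
"""

from __future__ import annotations

from importlib import resources

from .correction import ScreeningTable

__all__ = [
    "MST_YEARS",
    "INTERVAL_YEARS",
    "DEFAULT_CUTOFFS",
    "REFERRAL_THRESHOLD",
    "PUBLISHED_LAMBDA1",
    "PUBLISHED_POOLED_LAMBDA1",
    "load_fixture",
]

#: Mean sojourn time (years) estimated for prostate cancer in the Finnish
#: trial; the correction takes it as a known constant.
MST_YEARS = 6.75

#: Inter-screen interval (years) over which interval cancers were ascertained.
INTERVAL_YEARS = 4.0

#: PSA cutoffs (ng/ml) whose published metric rows are reproducible from the
#: grouped fixture.  (Cutoffs 6 and 10 need the unpublished case split above
#: 4 ng/ml and are therefore not resolvable here.)
DEFAULT_CUTOFFS = (1.0, 2.0, 2.5, 3.0, 3.5, 4.0)

#: PSA level at/above which men were referred for biopsy in the first round.
REFERRAL_THRESHOLD = 4.0

#: Published pre-clinical incidence rates (per person-year) for the six
#: strata below 4 ng/ml, in stratum order.  The values for strata >= 2.5
#: ng/ml are not reproduced by homogeneous-model inversion of the stratum
#: interval-cancer proportions (the published estimation was age-stratified),
#: so the pipeline accepts them as supplied rates.
PUBLISHED_LAMBDA1 = (0.000528, 0.002779, 0.005128, 0.012479, 0.018583, 0.018225)

#: Published pooled rate over all strata below 4 ng/ml (18,954 men).
PUBLISHED_POOLED_LAMBDA1 = 0.003258

#: Published per-stratum PCDP prevalence (4 dp) and expected case counts,
#: plus the pooled row, as (p_pcdp, cases); used by ``reproduce``.
PUBLISHED_PCDP_TABLE = (
    (0.0036, 34),
    (0.0188, 115),
    (0.0346, 46),
    (0.0842, 69),
    (0.1254, 78),
    (0.1230, 54),
)
PUBLISHED_POOLED_PCDP = (0.0220, 417)

#: Published metric rows (sensitivity, specificity, PPV, NPV, Youden; %,
#: 1 dp) by cutoff, uncorrected and corrected.
PUBLISHED_UNCORRECTED = {
    1.0: (99.3, 48.1, 6.4, 99.9, 47.4),
    2.0: (96.9, 78.6, 13.9, 99.9, 75.5),
    2.5: (95.9, 85.3, 18.9, 99.8, 81.2),
    3.0: (94.4, 89.4, 24.1, 99.8, 83.8),
    3.5: (89.3, 92.3, 29.3, 99.6, 81.6),
    4.0: (86.3, 94.4, 35.5, 99.5, 80.7),
}
PUBLISHED_CORRECTED = {
    1.0: (94.7, 48.0, 6.4, 99.6, 42.8),
    2.0: (80.2, 78.5, 13.9, 98.9, 58.6),
    2.5: (75.3, 85.2, 18.9, 98.7, 60.5),
    3.0: (68.8, 89.2, 24.1, 98.3, 58.1),
    3.5: (60.3, 92.2, 29.3, 97.7, 52.5),
    4.0: (55.4, 94.3, 35.5, 97.4, 49.7),
}


def load_fixture() -> ScreeningTable:
    """The packaged Finnish first-round screening table."""
    from .io import load_screening_table

    path = resources.files("sojournroc.data").joinpath("finnish_first_round.csv")
    with resources.as_file(path) as p:
        table = load_screening_table(p, interval_years=INTERVAL_YEARS)
    assert table.n_total == 20687
    return table
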