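"""Contingency logic, PCDP estimation and the sojourn-time correction."""

import math

import pytest

from sojournroc.correction import (
    PSAStratum,
    ScreeningTable,
    contingency_at_cutoff,
    corrected_metrics,
    estimate_pcdp_by_stratum,
    metrics_table,
    pooled_pcdp,
    uncorrected_metrics,
)
from sojournroc.fixtures import MST_YEARS, PUBLISHED_LAMBDA1, PUBLISHED_POOLED_LAMBDA1

CUTOFFS = (1.0, 2.0, 2.5, 3.0, 3.5, 4.0)


class TestDomainTypes:
    def test_stratum_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            PSAStratum(0.0, 1.0, 10, 8, 5)  # cases exceed participants
        with pytest.raises(ValueError):
            PSAStratum(1.0, 1.0, 10, 0, 0)  # empty interval
        with pytest.raises(ValueError):
            PSAStratum(0.0, 1.0, 10, -1, 0)

    def test_table_requires_contiguous_cover(self):
        a = PSAStratum(0.0, 2.0, 10, 0, 0)
        gap = PSAStratum(3.0, math.inf, 10, 0, 0)
        with pytest.raises(ValueError, match="contiguous"):
            ScreeningTable((a, gap), 4.0)
        finite_end = PSAStratum(2.0, 4.0, 10, 0, 0)
        with pytest.raises(ValueError, match="infinity"):
            ScreeningTable((a, finite_end), 4.0)


class TestContingency:
    def test_fixture_at_cutoff_3(self, fixture_table):
        assert contingency_at_cutoff(fixture_table, 3.0) == (673, 40, 2124, 17850)

    def test_fixture_at_cutoff_4(self, fixture_table):
        tp, fn, fp, tn = contingency_at_cutoff(fixture_table, 4.0)
        assert (tp, fn) == (615, 98)
        assert tp + fn == 713 and fp + tn == 19974

    def test_cutoff_zero_everything_positive(self, fixture_table):
        tp, fn, fp, tn = contingency_at_cutoff(fixture_table, 0.0)
        assert fn == 0 and tn == 0
        assert tp == 713 and fp == 19974

    def test_interior_cutoff_rejected_with_neighbours(self, fixture_table):
        with pytest.raises(ValueError, match="3.5 and 4.0"):
            contingency_at_cutoff(fixture_table, 3.7)

    def test_cutoffs_above_referral_unresolvable_on_fixture(self, fixture_table):
        # the case split above 4 ng/ml is a single stratum: 6 and 10 ng/ml
        # cannot be resolved and must fail loudly
        for c in (6.0, 10.0):
            with pytest.raises(ValueError, match="not a stratum boundary"):
                contingency_at_cutoff(fixture_table, c)


class TestUncorrectedMetrics:
    @pytest.mark.parametrize(
        "cutoff, sens, spec",
        [(1.0, 99.3, 48.1), (3.0, 94.4, 89.4), (4.0, 86.3, 94.4)],
    )
    def test_published_operating_points(self, fixture_table, cutoff, sens, spec):
        p = uncorrected_metrics(fixture_table, cutoff)
        assert p.sensitivity == pytest.approx(sens, abs=0.05)
        assert p.specificity == pytest.approx(spec, abs=0.05)

    def test_youden_identity_and_range(self, fixture_table):
        for c in CUTOFFS:
            p = uncorrected_metrics(fixture_table, c)
            assert p.youden == pytest.approx(p.sensitivity + p.specificity - 100, abs=1e-9)
            for v in (p.sensitivity, p.specificity, p.ppv, p.npv):
                assert 0.0 <= v <= 100.0

    def test_degenerate_margin_rejected(self, fixture_table):
        with pytest.raises(ValueError, match="empty"):
            uncorrected_metrics(fixture_table, 0.0)  # no test negatives


class TestEstimatePCDP:
    def test_supplied_rates_reproduce_expected_counts(self, published_pcdp):
        expected = [34.26, 114.65, 46.45, 69.24, 78.15, 54.25]
        got = [e.expected_cases for e in published_pcdp]
        assert got == pytest.approx(expected, abs=0.02)
        assert sum(got) == pytest.approx(397.0, abs=0.05)
        for e in published_pcdp:
            assert e.expected_cases == e.stratum.n_participants * e.p_pcdp
            assert e.p_pcdp == e.lambda1 * MST_YEARS

    def test_inverted_rates_follow_interval_cancer_gradient(self, fixture_table):
        ests = estimate_pcdp_by_stratum(fixture_table, MST_YEARS, "invert-exact")
        assert len(ests) == 6
        # rate roughly tracks the stratum interval-cancer proportion
        p_ics = [e.p_ic for e in ests]
        lams = [e.lambda1 for e in ests]
        assert sorted(range(6), key=lambda i: p_ics[i]) == sorted(
            range(6), key=lambda i: lams[i]
        )
        # lowest stratum: homogeneous inversion ~ published value
        assert ests[0].lambda1 == pytest.approx(0.000528, rel=0.01)

    def test_zero_interval_cancers_give_zero_rate(self):
        table = ScreeningTable(
            (
                PSAStratum(0.0, 4.0, 1000, 0, 0),
                PSAStratum(4.0, math.inf, 100, 50, 5),
            ),
            4.0,
        )
        (est,) = estimate_pcdp_by_stratum(table, 6.75, "invert-exact")
        assert est.lambda1 == 0.0 and est.expected_cases == 0.0

    def test_supplied_list_length_checked(self, fixture_table):
        with pytest.raises(ValueError, match="length"):
            estimate_pcdp_by_stratum(fixture_table, MST_YEARS, (0.001, 0.002))

    def test_zero_participant_stratum_rejected(self):
        table = ScreeningTable(
            (
                PSAStratum(0.0, 4.0, 0, 0, 0),
                PSAStratum(4.0, math.inf, 100, 50, 5),
            ),
            4.0,
        )
        with pytest.raises(ValueError, match="zero participants"):
            estimate_pcdp_by_stratum(table, 6.75, "invert-exact")

    def test_pooled_row_is_independent_aggregate(self, fixture_table):
        pooled = pooled_pcdp(fixture_table, MST_YEARS, PUBLISHED_POOLED_LAMBDA1)
        assert pooled.stratum.n_participants == 18954
        assert pooled.expected_cases == pytest.approx(416.8, abs=0.1)
        # pooling is not the sum of the stratum-wise estimates
        stratum_sum = sum(
            e.expected_cases
            for e in estimate_pcdp_by_stratum(
                fixture_table, MST_YEARS, PUBLISHED_LAMBDA1
            )
        )
        assert abs(pooled.expected_cases - stratum_sum) > 10


class TestCorrectedMetrics:
    def test_worked_example_cutoff_1(self, fixture_table, published_pcdp):
        p = corrected_metrics(fixture_table, 1.0, published_pcdp)
        assert p.sensitivity == pytest.approx(100 * 708 / (713 + 34.27), abs=0.01)

    def test_cutoff_3_uses_only_below_cutoff_mass(self, fixture_table, published_pcdp):
        p = corrected_metrics(fixture_table, 3.0, published_pcdp)
        x = 34.27 + 114.65 + 46.45 + 69.24
        assert p.sensitivity == pytest.approx(100 * 673 / (713 + x), abs=0.01)
        assert p.specificity == pytest.approx(
            100 * (17850 - x) / (19709.39), abs=0.01
        )

    def test_zero_mass_leaves_metrics_unchanged(self, fixture_table, published_pcdp):
        zero = [
            type(e)(stratum=e.stratum, lambda1=0.0, p_pcdp=0.0, expected_cases=0.0)
            for e in published_pcdp
        ]
        for c in CUTOFFS:
            u = uncorrected_metrics(fixture_table, c)
            k = corrected_metrics(fixture_table, c, zero)
            assert k.sensitivity == pytest.approx(u.sensitivity)
            assert k.specificity == pytest.approx(u.specificity)

    def test_excess_mass_rejected(self, fixture_table, published_pcdp):
        blown = [
            type(e)(
                stratum=e.stratum,
                lambda1=e.lambda1,
                p_pcdp=e.p_pcdp,
                expected_cases=e.expected_cases * 1e3,
            )
            for e in published_pcdp
        ]
        with pytest.raises(ValueError, match="exceeds"):
            corrected_metrics(fixture_table, 4.0, blown)


class TestMetricsTable:
    def test_empty_cutoff_list(self, fixture_table):
        assert metrics_table(fixture_table, (), MST_YEARS, PUBLISHED_LAMBDA1) == []

    def test_ordering_and_variants(self, fixture_table):
        pts = metrics_table(fixture_table, CUTOFFS, MST_YEARS, PUBLISHED_LAMBDA1)
        assert [(p.cutoff, p.variant) for p in pts] == [
            (c, v) for c in CUTOFFS for v in ("corrected", "uncorrected")
        ]

    def test_monotonicity_in_cutoff(self, fixture_table):
        pts = metrics_table(fixture_table, CUTOFFS, MST_YEARS, PUBLISHED_LAMBDA1)
        for variant in ("uncorrected", "corrected"):
            sel = [p for p in pts if p.variant == variant]
            sens = [p.sensitivity for p in sel]
            spec = [p.specificity for p in sel]
            assert all(b <= a for a, b in zip(sens, sens[1:]))
            assert all(b >= a for a, b in zip(spec, spec[1:]))

    def test_correction_dominance_and_ppv_identity(self, fixture_table):
        pts = metrics_table(fixture_table, CUTOFFS, MST_YEARS, PUBLISHED_LAMBDA1)
        by_cutoff = {
            c: {p.variant: p for p in pts if p.cutoff == c} for c in CUTOFFS
        }
        for c, d in by_cutoff.items():
            assert d["corrected"].sensitivity < d["uncorrected"].sensitivity
            assert d["corrected"].specificity < d["uncorrected"].specificity
            assert d["corrected"].ppv == pytest.approx(d["uncorrected"].ppv, abs=1e-9)
            # test-negative margin is conserved by the correction
            assert d["corrected"].fn + d["corrected"].tn == pytest.approx(
                d["uncorrected"].fn + d["uncorrected"].tn
            )

    def test_corrected_youden_peaks_at_2p5(self, fixture_table):
        pts = metrics_table(fixture_table, CUTOFFS, MST_YEARS, PUBLISHED_LAMBDA1)
        corrected = [p for p in pts if p.variant == "corrected"]
        best = max(corrected, key=lambda p: p.youden)
        assert best.cutoff == 2.5
        uncorrected = [p for p in pts if p.variant == "uncorrected"]
        assert max(uncorrected, key=lambda p: p.youden).cutoff == 3.0

    def test_case_margin_constant_uncorrected(self, fixture_table):
        pts = metrics_table(fixture_table, CUTOFFS, MST_YEARS, PUBLISHED_LAMBDA1)
        margins = {p.tp + p.fn for p in pts if p.variant == "uncorrected"}
        assert margins == {713}
        # corrected margin includes full expected mass once all strata are below
        top = [p for p in pts if p.variant == "corrected" and p.cutoff == 4.0][0]
        assert top.tp + top.fn == pytest.approx(713 + 397.0, abs=0.05)
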