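"""Allelic 2x2 statistics and risk-allele harmonization."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from evsyn.stats import (
    AlleleTable2x2,
    Basis,
    TestMethod as ChiMethod,
    UndefinedEstimateError,
    alleles_from_genotypes,
    allelic_chi2_p,
    allelic_odds_ratio,
    harmonize_risk_allele,
    select_reported_association,
)
from evsyn.types import Design, Domain, ReportedModel, StudyRecord, VariantKey


def make_record(**kw):
    variant = kw.pop(
        "variant",
        VariantKey(variant_id="rsX", gene="GENE", allele_a="G", allele_b="A"),
    )
    base = dict(
        pub_id="pub1",
        variant=variant,
        design=Design.CANDIDATE,
        domain=Domain.SUSCEPTIBILITY,
        n_case=100,
        n_control=100,
    )
    base.update(kw)
    return StudyRecord(**base)


class TestAllelesFromGenotypes:
    @pytest.mark.parametrize(
        "gc, expected",
        [
            ((10, 0, 0, 5, 5, 5), (20, 0, 15, 15)),
            ((10, 20, 5, 1, 2, 3), (40, 30, 4, 8)),
        ],
    )
    def test_collapse(self, gc, expected):
        assert alleles_from_genotypes(gc) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            alleles_from_genotypes((10, 10, 10, 0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            alleles_from_genotypes((-1, 0, 0, 1, 1, 1))


class TestOddsRatio:
    def test_symmetric_table_is_null(self):
        or_hat, lo, hi = allelic_odds_ratio(AlleleTable2x2(10, 10, 10, 10))
        assert or_hat == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example(self):
        # oracle: 30*85/(70*15) and Woolf CI computed independently
        or_hat, lo, hi = allelic_odds_ratio(AlleleTable2x2(30, 70, 15, 85))
        assert or_hat == pytest.approx(2.4286, abs=1e-4)
        assert lo == pytest.approx(1.211, abs=1e-3)
        assert hi == pytest.approx(4.870, abs=1e-3)

    def test_zero_cell_haldane_correction(self):
        # oracle: (5.5*7.5)/(0.5*3.5) after +0.5 on all cells
        or_hat, lo, hi = allelic_odds_ratio(AlleleTable2x2(5, 0, 3, 7))
        assert math.isfinite(or_hat)
        assert or_hat == pytest.approx(41.25 / 1.75, rel=1e-12)
        assert lo <= or_hat <= hi

    def test_empty_group_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            allelic_odds_ratio(AlleleTable2x2(0, 0, 5, 5))

    @given(
        st.tuples(*[st.integers(1, 200)] * 4),
        st.integers(2, 9),
    )
    @settings(max_examples=100, deadline=None)
    def test_transpose_and_scaling_invariances(self, cells, k):
        a, b, c, d = cells
        or1 = allelic_odds_ratio(AlleleTable2x2(a, b, c, d))[0]
        or_swapped = allelic_odds_ratio(AlleleTable2x2(c, d, a, b))[0]
        assert or_swapped == pytest.approx(1 / or1, rel=1e-9)
        or_scaled = allelic_odds_ratio(AlleleTable2x2(k * a, k * b, c, d))[0]
        assert or_scaled == pytest.approx(or1, rel=1e-9)


class TestChiSquare:
    def test_independence_gives_p_one(self):
        assert allelic_chi2_p(AlleleTable2x2(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_worked_example(self):
        # oracle: n(ad-bc)^2/(r1 r2 c1 c2) = 6.4516 computed by hand
        p = allelic_chi2_p(AlleleTable2x2(30, 70, 15, 85))
        assert p == pytest.approx(0.01108, abs=2e-4)

    def test_group_label_symmetry(self):
        t = AlleleTable2x2(13, 42, 29, 8)
        assert allelic_chi2_p(t) == pytest.approx(
            allelic_chi2_p(t.swapped_groups()), rel=1e-12
        )

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            allelic_chi2_p(AlleleTable2x2(0, 5, 0, 5))

    def test_exhaustive_small_tables_match_independent_oracle(self):
        """Pearson statistic agrees with scipy's contingency machinery over
        every non-degenerate table with all cells <= 6."""
        from scipy.stats import chi2 as chi2_dist

        for a, b, c, d in itertools.product(range(7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            stat_oracle = chi2_contingency(
                [[a, b], [c, d]], correction=False
            ).statistic
            p_ours = allelic_chi2_p(AlleleTable2x2(a, b, c, d))
            assert p_ours == pytest.approx(
                float(chi2_dist.sf(stat_oracle, 1)), abs=1e-9
            )

    def test_yates_and_fisher_options(self):
        t = AlleleTable2x2(5, 15, 12, 8)
        p_pearson = allelic_chi2_p(t)
        p_yates = allelic_chi2_p(t, ChiMethod.YATES)
        p_fisher = allelic_chi2_p(t, ChiMethod.FISHER)
        oracle = chi2_contingency([[5, 15], [12, 8]], correction=True).pvalue
        assert p_yates == pytest.approx(float(oracle), abs=1e-9)
        assert p_pearson < p_yates
        assert 0 < p_fisher <= 1


class TestHarmonizeRiskAllele:
    def test_protective_report_flips(self):
        # a study reporting the alternate allele with OR < 1 implicates the
        # reference allele; opposite-strand reports are recognised for SNVs
        rec = make_record(
            variant=VariantKey(variant_id="rs6311", gene="HTR2A", allele_a="G", allele_b="A"),
            reported_risk_allele="T",
            or_value=0.722,
            p_value=0.006,
        )
        assert harmonize_risk_allele(rec) == ("G", Basis.REPORTED_OR_DIRECTION)

    def test_protective_same_strand(self):
        rec = make_record(
            variant=VariantKey(variant_id="rs2715148", gene="PCLO", allele_a="A", allele_b="C"),
            reported_risk_allele="A",
            or_value=0.79,
            p_value=1e-6,
        )
        assert harmonize_risk_allele(rec)[0] == "C"

    def test_raw_counts_dominate_and_tie_is_none(self):
        rec = make_record(
            allele_counts=(40, 160, 120, 80),
            raw_data_available=True,
            reported_risk_allele="G",
            or_value=2.0,
        )
        allele, basis = harmonize_risk_allele(rec)
        assert (allele, basis) == ("A", Basis.RAW_COUNTS)
        tie = make_record(allele_counts=(100, 100, 100, 100), raw_data_available=True)
        assert harmonize_risk_allele(tie)[0] is None

    def test_genotype_report_basis(self):
        rec = make_record(
            reported_risk_allele="A",
            reported_model=ReportedModel.GENOTYPIC,
            or_value=2.05,
            p_value=0.015,
        )
        assert harmonize_risk_allele(rec) == ("A", Basis.REPORTED_GENOTYPE)

    def test_no_direction_returns_none(self):
        rec = make_record(p_value=0.01)
        assert harmonize_risk_allele(rec) == (None, Basis.UNKNOWN)

    def test_raw_direction_matches_or_sign(self):
        from evsyn.stats import allele_table_for_study

        rec = make_record(allele_counts=(90, 110, 120, 80), raw_data_available=True)
        allele, _ = harmonize_risk_allele(rec)
        table = allele_table_for_study(rec, allele)
        or_hat = allelic_odds_ratio(table)[0]
        assert or_hat > 1


class TestSelectReportedAssociation:
    def test_raw_counts_preferred_over_genotypic_report(self):
        rec = make_record(
            allele_counts=(60, 140, 120, 80),
            raw_data_available=True,
            reported_model=ReportedModel.GENOTYPIC,
            reported_risk_allele="A",
            or_value=3.0,
            p_value=0.2,
        )
        res = select_reported_association(rec)
        assert res.basis is Basis.RAW_COUNTS
        assert res.significant
        assert res.or_hat != 3.0

    def test_reported_fallback_threshold(self):
        rec = make_record(reported_risk_allele="A", or_value=1.5, p_value=0.20)
        res = select_reported_association(rec)
        assert not res.significant and res.p_allelic == 0.20

    def test_genotype_counts_collapse_to_allelic_test(self):
        # oracle: genotype triplets (30,40,30)/(50,40,10) collapse to allele
        # counts (100,100)/(140,60); chi-square on that table by hand = 16.667
        rec = make_record(
            genotype_counts=(30, 40, 30, 50, 40, 10),
            raw_data_available=True,
        )
        res = select_reported_association(rec)
        assert res.risk_allele == "A"
        assert res.p_allelic == pytest.approx(4.46e-5, rel=5e-3)

    def test_unassessable_record_returns_none(self):
        rec = make_record(reported_risk_allele="A", or_value=1.4)
        assert select_reported_association(rec) is None

    def test_frequency_reconstruction(self):
        rec = make_record(
            case_freq_b=0.40,
            ctrl_freq_b=0.25,
            raw_data_available=True,
        )
        res = select_reported_association(rec)
        assert res.basis is Basis.RECONSTRUCTED_FREQS
        assert res.risk_allele == "A" and res.significant
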