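"""Replication grouping, MAF filter, evidence buckets, consistency."""

import pytest

from evsyn.replication import (
    Bucket,
    Consistency,
    Level,
    assess_consistency,
    bucket_counts,
    classify_evidence,
    consistency_tally,
    filter_maf,
    filter_replicated,
    group_records,
    stratify_response,
)
from evsyn.types import Catalog, Design, Domain, StudyRecord, VariantKey


def make_variant(vid="rsX", a="G", b="A", gene="GENE"):
    return VariantKey(variant_id=vid, gene=gene, allele_a=a, allele_b=b)


def make_record(vid="rsX", pub="p1", design=Design.CANDIDATE, p=0.01, **kw):
    base = dict(
        pub_id=pub,
        variant=kw.pop("variant", make_variant(vid)),
        design=design,
        domain=Domain.SUSCEPTIBILITY,
        n_case=100,
        n_control=100,
        reported_risk_allele=kw.pop("risk", "A"),
        or_value=kw.pop("or_value", 1.5),
        p_value=p,
    )
    base.update(kw)
    return StudyRecord(**base)


def by_key(groups):
    return {g.key: g for g in groups}


def test_empty_catalog_gives_no_groups():
    assert group_records(Catalog(records=[])) == []


def test_nonsignificant_records_excluded():
    cat = Catalog(records=[make_record(pub="a", p=0.01), make_record(pub="b", p=0.2)])
    groups = group_records(cat)
    assert groups[0].n_countable == 1


def test_same_publication_strata_collapse(mdd_catalog):
    groups = by_key(group_records(mdd_catalog, "variant", "mdd"))
    # two menopausal strata of one publication count once
    g = groups["rs1801133"]
    assert len(g.studies) == 5 and g.n_countable == 4
    g = groups["rs6265"]
    assert g.n_countable == 8


def test_same_cohort_publications_collapse(response_catalog):
    groups = by_key(group_records(response_catalog, "variant", "response"))
    g = groups["rs6295"]
    assert g.n_pubs == 4  # displayed bracket count
    assert g.n_countable == 3  # two reports share one Taiwanese cohort


def test_filter_replicated_threshold(mdd_catalog):
    groups = group_records(mdd_catalog, "variant", "mdd")
    kept2 = by_key(filter_replicated(groups, 2))
    singleton = Catalog(records=[make_record()])
    assert filter_replicated(group_records(singleton), 2) == []
    assert "5-HTTLPR" in kept2
    kept3 = by_key(filter_replicated(groups, 3))
    assert "5-HTTLPR" in kept3 and "rs1006737" not in kept3
    with pytest.raises(ValueError):
        filter_replicated(groups, 0)


class TestMafFilter:
    def test_named_low_maf_exclusions(self, mdd_catalog):
        groups = filter_replicated(group_records(mdd_catalog, "variant", "mdd"))
        kept, excluded = filter_maf(groups)
        assert {g.key for g in excluded} == {"rs120074175", "rs6195", "rs6189+rs6190"}
        assert by_key(kept)["rs6265"].maf_global == 0.20

    def test_boundary_is_strict(self):
        cat = Catalog(
            records=[
                make_record(pub="a", maf_global=0.05),
                make_record(pub="b", maf_global=0.05),
            ]
        )
        kept, excluded = filter_maf(group_records(cat))
        assert len(kept) == 1 and not excluded

    def test_absent_maf_kept(self, response_catalog):
        groups = filter_replicated(group_records(response_catalog, "variant", "response"))
        kept, excluded = filter_maf(groups)
        assert "STin2" in by_key(kept) and not excluded

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            filter_maf([], threshold=0.7)


class TestBuckets:
    def test_fixture_bucket_examples(self, mdd_bundle):
        groups = by_key(mdd_bundle.variant_groups)
        assert classify_evidence(groups["rs2522833"]) == {Bucket.CANDIDATE, Bucket.BOTH}
        assert classify_evidence(groups["rs2273289"]) == {Bucket.GWAS}
        assert classify_evidence(groups["rs2715147"]) == {Bucket.BOTH}

    def test_mixed_pair_is_both_only(self, response_bundle):
        groups = by_key(response_bundle.variant_groups)
        assert classify_evidence(groups["rs6127921"]) == {Bucket.BOTH}

    def test_bucket_soundness_property(self, mdd_bundle, response_bundle):
        for g in mdd_bundle.variant_groups + response_bundle.variant_groups:
            buckets = classify_evidence(g)
            if Bucket.BOTH in buckets:
                assert g.n_candidate >= 1 and g.n_gwas >= 1
            if Bucket.CANDIDATE in buckets and Bucket.BOTH not in buckets:
                assert g.n_gwas == 0

    def test_bucket_counts_report_sum_and_unique(self, mdd_bundle):
        counts = bucket_counts(mdd_bundle.variant_groups)
        assert counts["bucket_sum"] == sum(
            counts[b] for b in ("candidate", "gwas", "both")
        )
        assert counts["unique"] == len(mdd_bundle.variant_groups)


class TestConsistency:
    def test_uniform_alleles_consistent(self, mdd_bundle):
        groups = by_key(mdd_bundle.variant_groups)
        status = assess_consistency(groups["rs1801133"])
        assert status.status is Consistency.CONSISTENT and status.modal_allele == "T"

    def test_split_report_inconsistent(self, mdd_bundle):
        groups = by_key(mdd_bundle.variant_groups)
        st = assess_consistency(groups["5-HTTLPR"])
        assert st.status is Consistency.INCONSISTENT
        alleles = [s.risk_allele for s in groups["5-HTTLPR"].studies]
        assert alleles.count("S") == 7 and alleles.count("L") == 3

    def test_single_study_undetermined(self):
        cat = Catalog(records=[make_record()])
        st = assess_consistency(group_records(cat)[0])
        assert st.status is Consistency.UNDETERMINED

    def test_order_invariance(self, mdd_bundle):
        import random

        for g in mdd_bundle.variant_groups:
            ref = assess_consistency(g).status
            shuffled = list(g.studies)
            random.Random(7).shuffle(shuffled)
            g2 = type(g)(key=g.key, level=g.level, variant=g.variant, studies=shuffled)
            assert assess_consistency(g2).status is ref

    def test_listing_tally_matches_bucket_sum(self, mdd_bundle):
        tally = consistency_tally(mdd_bundle.variant_groups)
        counts = bucket_counts(mdd_bundle.variant_groups)
        assert tally["consistent"] + tally["inconsistent"] == counts["bucket_sum"]


class TestStratification:
    def test_response_strata_partition(self, response_bundle):
        for g in response_bundle.variant_groups:
            strata = stratify_response(g)
            pooled = [s for studies in strata.values() for s in studies]
            assert sorted(id(s) for s in pooled) == sorted(id(s) for s in g.studies)

    def test_5httlpr_strata_structure(self, response_bundle):
        g = by_key(response_bundle.variant_groups)["5-HTTLPR"]
        strata = stratify_response(g)
        keys = {
            (k.domain.value, k.drug_class.value, k.risk_allele) for k in strata
        }
        assert ("response", "SSRI", "S") in keys
        assert ("response", "SSRI", "L") in keys
        assert ("remission", "SSRI", "S") in keys
        assert ("response", "TCA", "L") in keys

    def test_single_stratum_identity(self):
        cat = Catalog(records=[make_record(pub="a"), make_record(pub="b")])
        g = group_records(cat)[0]
        from evsyn.replication import stratify

        strata = stratify(g)
        assert len(strata) == 1 and len(next(iter(strata.values()))) == 2


def test_monotonicity_under_added_significant_study(mdd_catalog):
    """Adding a significant study never shrinks the replicated set."""
    base_groups = filter_replicated(group_records(mdd_catalog, "variant", "mdd"))
    base_keys = {g.key for g in base_groups}
    extra = make_record(
        vid="rs6265",
        pub="new_study",
        variant=next(
            r.variant for r in mdd_catalog.records if r.variant.variant_id == "rs6265"
        ),
        maf_global=0.20,
    )
    bigger = Catalog(records=list(mdd_catalog.records) + [extra])
    new_keys = {g.key for g in filter_replicated(group_records(bigger, "variant", "mdd"))}
    assert base_keys <= new_keys
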