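"""Replication grouping, MAF filtering, evidence buckets and consistency.

A variant (or gene) counts as *replicated* when significant association was
reported in at least two independent studies.  Independence is counted at the
cohort level: records from the same publication (different strata) and
publications re-analysing the same participant cohort collapse to one
countable study.  Replicated variants are classified by study design into
evidence buckets — ``candidate`` (>=2 candidate studies), ``gwas`` (>=2 GWAS
studies) and ``both`` (>=1 of each); a variant may occupy several buckets, and
headline counts sum bucket sizes, so a variant supported by, say, two
candidate studies plus one GWAS contributes to both the candidate and the
"both" tallies (the deduplicated unique count is reported alongside).

Risk-allele *consistency* asks whether every contributing study's harmonized
risk allele is the same; the headline tally is taken per (variant, bucket)
listing, restricting a candidate listing to its candidate studies and a GWAS
listing to its GWAS studies, mirroring how the evidence tables are laid out.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .stats import ALPHA, AssocResult, TestMethod, select_reported_association
from .types import (
    Catalog,
    Design,
    Domain,
    DrugClass,
    RESPONSE_DOMAINS,
    StudyRecord,
    VariantKey,
)

logger = logging.getLogger(__name__)


class Level(str, enum.Enum):
    VARIANT = "variant"
    GENE = "gene"


class Bucket(str, enum.Enum):
    CANDIDATE = "candidate"
    GWAS = "gwas"
    BOTH = "both"


class Consistency(str, enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class AssessedStudy:
    """A significant study record with its harmonized association summary."""

    record: StudyRecord
    assoc: AssocResult

    @property
    def risk_allele(self) -> Optional[str]:
        return self.assoc.risk_allele


@dataclass(frozen=True)
class ConsistencyStatus:
    status: Consistency
    modal_allele: Optional[str] = None


@dataclass
class EvidenceGroup:
    """All significant studies for one variant (or gene) in one domain scope."""

    key: str  # variant_id or gene symbol
    level: Level
    variant: Optional[VariantKey]  # None at gene level
    studies: list[AssessedStudy] = field(default_factory=list)

    @property
    def n_pubs(self) -> int:
        return len({s.record.pub_id for s in self.studies})

    @property
    def n_countable(self) -> int:
        """Independent evidence count: unique cohorts."""
        return len({s.record.cohort for s in self.studies})

    @property
    def n_candidate(self) -> int:
        return len(
            {s.record.cohort for s in self.studies if s.record.design is Design.CANDIDATE}
        )

    @property
    def n_gwas(self) -> int:
        return len(
            {s.record.cohort for s in self.studies if s.record.design is Design.GWAS}
        )

    @property
    def maf_global(self) -> Optional[float]:
        for s in self.studies:
            if s.record.maf_global is not None:
                return s.record.maf_global
        return None

    def design_subset(self, design: Design) -> list[AssessedStudy]:
        return [s for s in self.studies if s.record.design is design]


def _domain_scope(domain: str | Domain) -> frozenset[Domain]:
    """Map a domain selector to the set of record domains it covers.

    ``susceptibility`` (or ``mdd``) selects disease-risk records; ``response``
    selects the whole treatment-outcome family (response, remission,
    resistance), which is analysed as one evidence base stratified later.
    """
    if isinstance(domain, Domain):
        if domain in RESPONSE_DOMAINS:
            return frozenset(RESPONSE_DOMAINS)
        return frozenset({domain})
    label = str(domain).lower()
    if label in ("mdd", "susceptibility", "disease"):
        return frozenset({Domain.SUSCEPTIBILITY})
    if label in ("response", "drug_response", "treatment"):
        return frozenset(RESPONSE_DOMAINS)
    raise ValueError(f"unknown domain selector {domain!r}")


def group_records(
    catalog: Catalog,
    level: Level | str = Level.VARIANT,
    domain: str | Domain = Domain.SUSCEPTIBILITY,
    alpha: float = ALPHA,
    method: TestMethod = TestMethod.PEARSON,
) -> list[EvidenceGroup]:
    """Group significant records by variant or gene within a domain scope.

    Non-significant and unassessable records are excluded (logged); groups
    preserve first-appearance order of their key.
    """
    level = Level(level)
    scope = _domain_scope(domain)
    groups: dict[str, EvidenceGroup] = {}
    for rec in catalog.records:
        if rec.domain not in scope:
            continue
        assoc = select_reported_association(rec, alpha=alpha, method=method)
        if assoc is None:
            logger.info(
                "excluding unassessable record %s/%s (no raw data, no reported P)",
                rec.pub_id,
                rec.variant.variant_id,
            )
            continue
        if not assoc.significant:
            logger.info(
                "excluding non-significant record %s/%s (p=%s)",
                rec.pub_id,
                rec.variant.variant_id,
                assoc.p_allelic,
            )
            continue
        key = rec.variant.variant_id if level is Level.VARIANT else rec.variant.gene
        grp = groups.get(key)
        if grp is None:
            grp = EvidenceGroup(
                key=key,
                level=level,
                variant=rec.variant if level is Level.VARIANT else None,
            )
            groups[key] = grp
        grp.studies.append(AssessedStudy(rec, assoc))
    return list(groups.values())


def filter_replicated(
    groups: Sequence[EvidenceGroup], min_studies: int = 2
) -> list[EvidenceGroup]:
    """Retain groups supported by at least ``min_studies`` independent cohorts."""
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    return [g for g in groups if g.n_countable >= min_studies]


def filter_maf(
    groups: Sequence[EvidenceGroup], threshold: float = 0.05
) -> tuple[list[EvidenceGroup], list[EvidenceGroup]]:
    """Split groups into (kept, excluded) by global MAF strictly below threshold.

    A group without a recorded global MAF is kept with a warning.
    """
    if not (0 < threshold <= 0.5):
        raise ValueError("MAF threshold must lie in (0, 0.5]")
    kept, excluded = [], []
    for g in groups:
        maf = g.maf_global
        if maf is None:
            logger.warning("group %s has no global MAF; kept", g.key)
            kept.append(g)
        elif maf < threshold:
            excluded.append(g)
        else:
            kept.append(g)
    return kept, excluded


def classify_evidence(group: EvidenceGroup) -> set[Bucket]:
    """Evidence buckets of a replicated group (overlap allowed)."""
    buckets: set[Bucket] = set()
    if group.n_candidate >= 2:
        buckets.add(Bucket.CANDIDATE)
    if group.n_gwas >= 2:
        buckets.add(Bucket.GWAS)
    if group.n_candidate >= 1 and group.n_gwas >= 1:
        buckets.add(Bucket.BOTH)
    return buckets


def _alleles_of(studies: Sequence[AssessedStudy]) -> list[Optional[str]]:
    return [s.risk_allele for s in studies]


def _consistency_of(
    studies: Sequence[AssessedStudy], undetermined_is_inconsistent: bool = True
) -> ConsistencyStatus:
    alleles = _alleles_of(studies)
    if len(studies) < 2:
        return ConsistencyStatus(Consistency.UNDETERMINED)
    if any(a is None for a in alleles):
        status = (
            Consistency.INCONSISTENT
            if undetermined_is_inconsistent
            else Consistency.UNDETERMINED
        )
        return ConsistencyStatus(status)
    uniq = set(alleles)
    if len(uniq) == 1:
        return ConsistencyStatus(Consistency.CONSISTENT, alleles[0])
    return ConsistencyStatus(Consistency.INCONSISTENT)


def assess_consistency(
    group: EvidenceGroup, undetermined_is_inconsistent: bool = True
) -> ConsistencyStatus:
    """Risk-allele consistency across all studies of a group.

    Consistent iff every study carries the same harmonized allele; any study
    without an inferable direction makes the group count as inconsistent for
    headline tallies (configurable).  Single-study groups are undetermined
    (they are not replicated anyway).
    """
    return _consistency_of(group.studies, undetermined_is_inconsistent)


def bucket_listings(
    groups: Sequence[EvidenceGroup],
) -> list[tuple[EvidenceGroup, Bucket, list[AssessedStudy]]]:
    """Expand groups into (group, bucket, studies) listings.

    A candidate listing carries the group's candidate studies, a GWAS listing
    its GWAS studies and a "both" listing all studies — the layout used by the
    published evidence tables, whose headline counts sum listings.
    """
    out = []
    for g in groups:
        for bucket in sorted(classify_evidence(g), key=lambda b: b.value):
            if bucket is Bucket.CANDIDATE:
                studies = g.design_subset(Design.CANDIDATE)
            elif bucket is Bucket.GWAS:
                studies = g.design_subset(Design.GWAS)
            else:
                studies = list(g.studies)
            out.append((g, bucket, studies))
    return out


def bucket_counts(groups: Sequence[EvidenceGroup]) -> dict[str, int]:
    """Headline bucket sizes plus bucket-sum and unique-variant counts."""
    counts = {b.value: 0 for b in Bucket}
    for _, bucket, _ in bucket_listings(groups):
        counts[bucket.value] += 1
    counts["bucket_sum"] = sum(counts[b.value] for b in Bucket)
    counts["unique"] = len(groups)
    return counts


def consistency_tally(
    groups: Sequence[EvidenceGroup], undetermined_is_inconsistent: bool = True
) -> dict[str, int]:
    """Listing-level consistent/inconsistent tally (sums to the bucket-sum)."""
    tally = {"consistent": 0, "inconsistent": 0}
    for _, _, studies in bucket_listings(groups):
        st = _consistency_of(studies, undetermined_is_inconsistent)
        if st.status is Consistency.CONSISTENT:
            tally["consistent"] += 1
        else:
            tally["inconsistent"] += 1
    return tally


@dataclass(frozen=True)
class StratumKey:
    """Pooling stratum: risk allele, plus outcome domain and drug class for
    treatment-response evidence (pooling never crosses those boundaries)."""

    risk_allele: Optional[str]
    domain: Optional[Domain] = None
    drug_class: Optional[DrugClass] = None


def stratify(group: EvidenceGroup) -> dict[StratumKey, list[AssessedStudy]]:
    """Partition a group's studies into pooling strata.

    Susceptibility evidence stratifies by harmonized risk allele only;
    response-family evidence additionally by (outcome domain, drug class).
    The strata are disjoint and cover the group.
    """
    out: dict[StratumKey, list[AssessedStudy]] = {}
    for s in group.studies:
        if s.record.domain in RESPONSE_DOMAINS:
            key = StratumKey(s.risk_allele, s.record.domain, s.record.drug_class)
        else:
            key = StratumKey(s.risk_allele)
        out.setdefault(key, []).append(s)
    return out


def stratify_response(group: EvidenceGroup) -> dict[StratumKey, list[AssessedStudy]]:
    """Alias of :func:`stratify` for response-domain groups."""
    if not all(s.record.domain in RESPONSE_DOMAINS for s in group.studies):
        raise ValueError("stratify_response expects response-family records")
    return stratify(group)
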