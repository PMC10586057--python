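"""Domain types for curated genetic-association evidence.

The package models the evidence base of case-control association studies of
major depressive disorder (MDD) susceptibility and antidepressant response:
each :class:`StudyRecord` is one published association result for one variant,
a :class:`Catalog` is an ordered collection of such records (optionally with
per-variant in-silico annotations), and downstream modules group, filter and
pool them.

Alleles are opaque strings so that non-SNV polymorphisms (the 5-HTTLPR 44-bp
insertion/deletion with "L"/"S" alleles, the STin2 VNTR with repeat-number
alleles) live in the same catalog as rsID SNVs.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "indel"
    VNTR = "VNTR"


class Design(str, enum.Enum):
    CANDIDATE = "candidate"
    GWAS = "gwas"


class Domain(str, enum.Enum):
    SUSCEPTIBILITY = "susceptibility"
    RESPONSE = "response"
    REMISSION = "remission"
    RESISTANCE = "resistance"


#: Domains describing treatment outcome rather than disease risk.
RESPONSE_DOMAINS = frozenset(
    {Domain.RESPONSE, Domain.REMISSION, Domain.RESISTANCE}
)


class DrugClass(str, enum.Enum):
    SSRI = "SSRI"
    SNRI = "SNRI"
    TCA = "TCA"
    ATYPICAL = "atypical"
    MIXED = "mixed"
    OTHER = "other"


class ReportedModel(str, enum.Enum):
    ALLELIC = "allelic"
    GENOTYPIC = "genotypic"
    UNKNOWN = "unknown"


class Directionality(str, enum.Enum):
    """Which printed group is the 'case' (risk) group of the 2x2 table.

    For susceptibility studies cases are the affected subjects; for
    response-domain studies the risk group is conventionally the
    non-responder / non-remitter arm and the fixture stores it as n_case.
    ``inverted`` flags records whose printed group order is the other way
    round, so 2x2 construction can swap the arms.
    """

    STANDARD = "standard"
    INVERTED = "inverted"


class SiftClass(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    NA = "na"


class PolyphenClass(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    NA = "na"


class VariantKey(BaseModel):
    """Identity of one polymorphism.

    ``allele_a``/``allele_b`` follow the catalog's reference/alternate
    orientation; no strand flipping is attempted on stored alleles (curated
    data are assumed consistent), although risk-allele harmonization will
    recognise an opposite-strand *reported* allele for SNVs.
    """

    model_config = ConfigDict(frozen=True)

    variant_id: str
    gene: str
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 1-based, GRCh38
    allele_a: str
    allele_b: str
    variant_class: VariantClass = VariantClass.SNV

    @model_validator(mode="after")
    def _check(self) -> "VariantKey":
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.allele_a == self.allele_b:
            raise ValueError(
                f"{self.variant_id}: allele_a and allele_b must differ"
            )
        if self.chrom is not None and self.pos is not None and self.pos <= 0:
            raise ValueError(f"{self.variant_id}: pos must be positive")
        return self

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    def other_allele(self, allele: str) -> str:
        if allele == self.allele_a:
            return self.allele_b
        if allele == self.allele_b:
            return self.allele_a
        raise ValueError(f"{allele!r} is not an allele of {self.variant_id}")


class StudyRecord(BaseModel):
    """One published association result for one variant in one stratum."""

    model_config = ConfigDict(frozen=True)

    pub_id: str
    cohort_id: Optional[str] = None  # defaults to pub_id when absent
    variant: VariantKey
    design: Design
    domain: Domain
    drug_class: Optional[DrugClass] = None
    outcome_scale: Optional[str] = None
    population: Optional[str] = None
    n_case: int
    n_control: int
    directionality: Directionality = Directionality.STANDARD
    genotype_counts: Optional[tuple[int, int, int, int, int, int]] = None
    allele_counts: Optional[tuple[int, int, int, int]] = None
    case_freq_b: Optional[float] = None
    ctrl_freq_b: Optional[float] = None
    reported_risk_allele: Optional[str] = None
    reported_model: ReportedModel = ReportedModel.UNKNOWN
    or_value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    maf_study: Optional[float] = None
    maf_global: Optional[float] = None
    raw_data_available: bool = False

    @field_validator("n_case", "n_control")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("group sizes must be positive")
        return v

    @field_validator("or_value")
    @classmethod
    def _or_pos(cls, v):
        if v is not None and v <= 0:
            raise ValueError("odds ratio must be positive")
        return v

    @field_validator("p_value")
    @classmethod
    def _p_domain(cls, v):
        if v is not None and not (0 < v <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        return v

    @field_validator("maf_study", "maf_global")
    @classmethod
    def _maf_domain(cls, v):
        if v is not None and not (0 <= v <= 0.5):
            raise ValueError("MAF must lie in [0, 0.5]")
        return v

    @model_validator(mode="after")
    def _check(self) -> "StudyRecord":
        pid = self.pub_id
        if self.genotype_counts is not None:
            gc = self.genotype_counts
            if any(c < 0 for c in gc):
                raise ValueError(f"{pid}: negative genotype count")
            if sum(gc[:3]) != self.n_case or sum(gc[3:]) != self.n_control:
                raise ValueError(
                    f"{pid}: genotype counts do not sum to group sizes"
                )
        if self.allele_counts is not None:
            ac = self.allele_counts
            if any(c < 0 for c in ac):
                raise ValueError(f"{pid}: negative allele count")
            if ac[0] + ac[1] != 2 * self.n_case or ac[2] + ac[3] != 2 * self.n_control:
                raise ValueError(
                    f"{pid}: allele counts do not sum to 2n per group"
                )
        if (
            self.or_value is not None
            and self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low <= self.or_value <= self.ci_high)
        ):
            raise ValueError(f"{pid}: CI does not bracket the odds ratio")
        for name in ("case_freq_b", "ctrl_freq_b"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"{pid}: {name} must lie in [0, 1]")
        return self

    @property
    def cohort(self) -> str:
        return self.cohort_id if self.cohort_id else self.pub_id

    @property
    def has_raw_counts(self) -> bool:
        """Raw data usable for recomputation: counts or both frequencies."""
        return self.raw_data_available and (
            self.allele_counts is not None
            or self.genotype_counts is not None
            or (self.case_freq_b is not None and self.ctrl_freq_b is not None)
        )


class RegulomeCategory(str, enum.Enum):
    """RegulomeDB 2.x ordinal rank; lower = stronger regulatory evidence."""

    R1A = "1a"
    R1B = "1b"
    R1C = "1c"
    R1D = "1d"
    R1E = "1e"
    R1F = "1f"
    R2A = "2a"
    R2B = "2b"
    R2C = "2c"
    R3A = "3a"
    R3B = "3b"
    R4 = "4"
    R5 = "5"
    R6 = "6"
    R7 = "7"
    NA = "na"


class AnnotationRecord(BaseModel):
    """Static in-silico annotation for one variant (no live queries)."""

    model_config = ConfigDict(frozen=True)

    variant_id: str
    missense_flag: bool = False
    sift_class: SiftClass = SiftClass.NA
    polyphen_class: PolyphenClass = PolyphenClass.NA
    regulome_rank: RegulomeCategory = RegulomeCategory.NA
    splice_flag: bool = False
    mirna_flag: bool = False
    conservation: Optional[float] = None  # in [0,1]
    reg_potential: Optional[float] = None  # in [0,1]
    ko_mouse: Optional[bool] = None
    drug_target: Optional[bool] = None
    brain_expressed: Optional[bool] = None

    @field_validator("conservation", "reg_potential")
    @classmethod
    def _unit_interval(cls, v):
        if v is not None and not (0 <= v <= 1):
            raise ValueError("score must lie in [0, 1]")
        return v


class Catalog(BaseModel):
    """Ordered collection of study records plus optional annotations."""

    records: list[StudyRecord]
    annotations: Optional[list[AnnotationRecord]] = None
    source: str = ""
    schema_version: str = "1"

    @model_validator(mode="after")
    def _check(self) -> "Catalog":
        keys = set()
        by_id: dict[str, VariantKey] = {}
        for i, rec in enumerate(self.records):
            key = (
                rec.pub_id,
                rec.variant.variant_id,
                rec.domain,
                rec.drug_class,
                rec.outcome_scale,
                rec.population,
                rec.n_case,
                rec.n_control,
            )
            if key in keys:
                raise ValueError(
                    f"duplicate record (row {i}): {rec.pub_id} / "
                    f"{rec.variant.variant_id} / {rec.domain.value}"
                )
            keys.add(key)
            seen = by_id.get(rec.variant.variant_id)
            if seen is None:
                by_id[rec.variant.variant_id] = rec.variant
            elif seen != rec.variant:
                raise ValueError(
                    f"variant_id {rec.variant.variant_id} maps to two "
                    "different variant keys"
                )
        return self

    def __len__(self) -> int:
        return len(self.records)

    def variants(self) -> dict[str, VariantKey]:
        out: dict[str, VariantKey] = {}
        for rec in self.records:
            out.setdefault(rec.variant.variant_id, rec.variant)
        return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(allele: str) -> str:
    """Reverse-complement of a plain nucleotide string."""
    return allele.translate(_COMPLEMENT)[::-1]
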