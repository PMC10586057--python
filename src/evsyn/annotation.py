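"""Summaries of static in-silico functional annotations.

Annotations (SIFT/PolyPhen-2 classes for missense variants, RegulomeDB
ordinal ranks, splice/miRNA-site flags, conservation and regulatory-potential
scores, knockout-mouse / antidepressant-drug-target / brain-expression flags)
are consumed from static tables only; nothing is queried at run time, so
summaries are reproducible against fixture snapshots.

A RegulomeDB rank of 5 or stronger counts as "predicted regulatory"; the
"high regulatory" tier defaults to a leading digit below 3 (ranks 1a–2c,
TF-binding-level evidence), configurable because published prose sometimes
draws the line at <=3a.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .types import (
    AnnotationRecord,
    PolyphenClass,
    RegulomeCategory,
    SiftClass,
)

_RANK_ORDER = [c for c in RegulomeCategory if c is not RegulomeCategory.NA]
_RANK_INDEX = {c: i for i, c in enumerate(_RANK_ORDER)}


@dataclass(frozen=True)
class RegulomeRank:
    """Validated, orderable RegulomeDB rank."""

    category: RegulomeCategory

    @property
    def numeric_part(self) -> Optional[int]:
        if self.category is RegulomeCategory.NA:
            return None
        return int(self.category.value[0])

    @property
    def is_na(self) -> bool:
        return self.category is RegulomeCategory.NA

    def __lt__(self, other: "RegulomeRank") -> bool:
        if self.is_na or other.is_na:
            raise TypeError("NA rank is unordered")
        return _RANK_INDEX[self.category] < _RANK_INDEX[other.category]

    def __le__(self, other: "RegulomeRank") -> bool:
        return self == other or self < other


def parse_rank(text: str) -> RegulomeRank:
    """Parse a rank string like '2b', '1f', '4' or 'NA'."""
    s = (text or "").strip().lower()
    if s in ("", "na", "-", "."):
        return RegulomeRank(RegulomeCategory.NA)
    try:
        return RegulomeRank(RegulomeCategory(s))
    except ValueError as exc:
        raise ValueError(f"unknown RegulomeDB rank {text!r}") from exc


@dataclass(frozen=True)
class AnnotationSummary:
    n_variants: int
    n_missense: int
    n_sift_deleterious: int
    n_polyphen_damaging: int
    frac_sift_deleterious: Optional[float]
    frac_polyphen_damaging: Optional[float]
    n_regulatory: int
    n_high_regulatory: int
    n_splice: int
    n_mirna: int
    n_conserved: int
    n_regpot: int
    n_ko_mouse: int
    n_drug_target: int
    n_brain: int
    frac_ko_mouse: Optional[float]
    frac_drug_target: Optional[float]
    frac_brain: Optional[float]


def summarize(
    annotations: Iterable[AnnotationRecord],
    variants: Optional[Sequence[str]] = None,
    regulatory_max_category: RegulomeCategory = RegulomeCategory.R5,
    high_regulatory_below: int = 3,
    conservation_threshold: float = 0.80,
    reg_potential_threshold: float = 0.40,
) -> AnnotationSummary:
    """Summary fractions over an annotation scope.

    ``variants`` restricts (and orders) the scope to the given variant_ids;
    annotation records for unknown variants are ignored.  Fractions are exact
    count/denominator ratios; nothing is stored pre-rounded.
    """
    records = list(annotations)
    if variants is not None:
        scope = set(variants)
        records = [r for r in records if r.variant_id in scope]
    n = len(records)
    missense = [r for r in records if r.missense_flag]
    n_missense = len(missense)
    n_sift = sum(1 for r in missense if r.sift_class is SiftClass.DELETERIOUS)
    n_poly = sum(
        1
        for r in missense
        if r.polyphen_class
        in (PolyphenClass.PROBABLY_DAMAGING, PolyphenClass.POSSIBLY_DAMAGING)
    )
    reg_cut = RegulomeRank(regulatory_max_category)
    ranks = [RegulomeRank(r.regulome_rank) for r in records]
    n_reg = sum(1 for rk in ranks if not rk.is_na and rk <= reg_cut)
    n_high = sum(
        1
        for rk in ranks
        if not rk.is_na and rk.numeric_part < high_regulatory_below
    )
    n_ko = sum(1 for r in records if r.ko_mouse)
    n_drug = sum(1 for r in records if r.drug_target)
    n_brain = sum(1 for r in records if r.brain_expressed)
    return AnnotationSummary(
        n_variants=n,
        n_missense=n_missense,
        n_sift_deleterious=n_sift,
        n_polyphen_damaging=n_poly,
        frac_sift_deleterious=n_sift / n_missense if n_missense else None,
        frac_polyphen_damaging=n_poly / n_missense if n_missense else None,
        n_regulatory=n_reg,
        n_high_regulatory=n_high,
        n_splice=sum(1 for r in records if r.splice_flag),
        n_mirna=sum(1 for r in records if r.mirna_flag),
        n_conserved=sum(
            1
            for r in records
            if r.conservation is not None and r.conservation > conservation_threshold
        ),
        n_regpot=sum(
            1
            for r in records
            if r.reg_potential is not None
            and r.reg_potential > reg_potential_threshold
        ),
        n_ko_mouse=n_ko,
        n_drug_target=n_drug,
        n_brain=n_brain,
        frac_ko_mouse=n_ko / n if n else None,
        frac_drug_target=n_drug / n if n else None,
        frac_brain=n_brain / n if n else None,
    )


def shortlist_annotation_join(
    shortlist_variants: Sequence[str],
    annotations: Iterable[AnnotationRecord],
) -> list[dict]:
    """One row per shortlist variant with its annotation fields.

    Boolean flags render as "Y"/"–" in the table-style output fields.
    """
    by_id = {r.variant_id: r for r in annotations}

    def yn(v: Optional[bool]) -> str:
        return "Y" if v else "–"

    rows = []
    for vid in shortlist_variants:
        r = by_id.get(vid)
        if r is None:
            rows.append({"variant_id": vid})
            continue
        rank = RegulomeRank(r.regulome_rank)
        rows.append(
            {
                "variant_id": vid,
                "regulome_rank": "–" if rank.is_na else r.regulome_rank.value,
                "splice_site": yn(r.splice_flag),
                "mirna": yn(r.mirna_flag),
                "sift": r.sift_class.value if r.missense_flag else "–",
                "polyphen": r.polyphen_class.value if r.missense_flag else "–",
                "conservation": r.conservation,
                "reg_potential": r.reg_potential,
                "knockout_mouse": yn(r.ko_mouse),
                "drug_target": yn(r.drug_target),
                "brain_expression": yn(r.brain_expressed),
            }
        )
    return rows
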