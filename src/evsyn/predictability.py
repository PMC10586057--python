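"""Pooled diagnostic predictability of replicated risk alleles.

Treating carriage of the risk allele as a diagnostic test for the phenotype
gives each study an allele-level confusion table: TP = risk alleles in cases,
FN = wild-type alleles in cases, FP = risk alleles in controls, TN = wild-type
alleles in controls (a carrier unit, counting subjects with >= 1 risk allele,
is available when genotype counts exist).  Studies that agree on the risk
allele — and, for treatment response, on outcome domain and drug class — are
pooled by element-wise summation, and

    sensitivity = sum TP / (sum TP + sum FN)
    specificity = sum TN / (sum TN + sum FP)
    PPV         = sum TP / (sum TP + sum FP)

No meta-analytic weighting is applied; the sums weight studies by their
allele counts.  Metrics are kept unrounded internally and displayed at two
decimals (round half-up).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .replication import AssessedStudy, EvidenceGroup, StratumKey, stratify
from .stats import allele_table_for_study
from .types import StudyRecord, VariantKey


class Unit(str, enum.Enum):
    ALLELE = "allele"
    CARRIER = "carrier"


class IneligibilityReason(str, enum.Enum):
    NO_RAW_DATA = "no_raw_data"
    SINGLETON_STRATUM = "singleton_stratum"
    DISCORDANT_ONLY = "discordant_only"


class UndefinedMetricError(ValueError):
    """A metric denominator is zero."""


@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fn: int
    tn: int
    fp: int
    unit: Unit = Unit.ALLELE

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class PredictabilityResult:
    key: str
    variant: Optional[VariantKey]
    stratum: StratumKey
    sensitivity: float
    specificity: float
    ppv: float
    confusion: Confusion2x2
    n_studies_pooled: int
    n_case_total: int
    n_ctrl_total: int


@dataclass(frozen=True)
class StratumEligibility:
    key: str
    stratum: StratumKey
    studies: tuple[AssessedStudy, ...]
    eligible: bool
    reason: Optional[IneligibilityReason] = None


def confusion_from_study(
    s: StudyRecord, risk_allele: str, unit: Unit = Unit.ALLELE
) -> Optional[Confusion2x2]:
    """Confusion table of one study oriented on ``risk_allele``.

    Returns None (an ineligibility signal, not an exception) when the study
    has no usable raw data, or when the carrier unit is requested without
    genotype counts.
    """
    if not s.raw_data_available:
        return None
    if unit is Unit.CARRIER:
        if s.genotype_counts is None or risk_allele not in s.variant.alleles:
            return None
        caa, cab, cbb, kaa, kab, kbb = s.genotype_counts
        if risk_allele == s.variant.allele_b:
            tp, fn, fp, tn = cab + cbb, caa, kab + kbb, kaa
        else:
            tp, fn, fp, tn = caa + cab, cbb, kaa + kab, kbb
        if s.directionality.value == "inverted":
            tp, fn, fp, tn = fp, tn, tp, fn
        return Confusion2x2(tp, fn, tn, fp, Unit.CARRIER)
    table = allele_table_for_study(s, risk_allele)
    if table is None:
        return None
    return Confusion2x2(
        tp=table.case_risk,
        fn=table.case_wild,
        tn=table.ctrl_wild,
        fp=table.ctrl_risk,
        unit=Unit.ALLELE,
    )


def pool(confusions: Sequence[Confusion2x2]) -> Confusion2x2:
    """Element-wise sum of confusion tables sharing a counting unit."""
    if not confusions:
        raise ValueError("cannot pool an empty collection")
    units = {c.unit for c in confusions}
    if len(units) > 1:
        raise ValueError("cannot pool mixed allele/carrier units")
    return Confusion2x2(
        tp=sum(c.tp for c in confusions),
        fn=sum(c.fn for c in confusions),
        tn=sum(c.tn for c in confusions),
        fp=sum(c.fp for c in confusions),
        unit=confusions[0].unit,
    )


def metrics(c: Confusion2x2) -> tuple[float, float, float]:
    """(sensitivity, specificity, PPV) of a confusion table, unrounded."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0 or c.tp + c.fp == 0:
        raise UndefinedMetricError(
            f"undefined metric for table tp={c.tp} fn={c.fn} tn={c.tn} fp={c.fp}"
        )
    return (
        c.tp / (c.tp + c.fn),
        c.tn / (c.tn + c.fp),
        c.tp / (c.tp + c.fp),
    )


def round_metric(x: float, ndigits: int = 2) -> float:
    """Display rounding, half-up (0.645 -> 0.65)."""
    q = 10**ndigits
    return math.floor(x * q + 0.5) / q


def eligible_strata(
    group: EvidenceGroup,
    min_pooled: int = 2,
    unit: Unit = Unit.ALLELE,
) -> list[StratumEligibility]:
    """Eligibility of each risk-allele stratum of a replicated group.

    A stratum is eligible when >= ``min_pooled`` independent cohorts in it
    have usable raw data.  Ineligible strata carry a reason code:
    ``singleton_stratum`` for a stratum below the pooling threshold (the
    typical fate of discordantly-reported variants, whose strata are all
    singletons), ``discordant_only`` for studies without an inferable risk
    allele, ``no_raw_data`` when the stratum is large enough but raw data
    are missing.
    """
    strata = stratify(group)
    out = []
    for key, studies in strata.items():
        if key.risk_allele is None:
            out.append(
                StratumEligibility(
                    group.key, key, tuple(studies), False,
                    IneligibilityReason.DISCORDANT_ONLY,
                )
            )
            continue
        with_raw = [
            s
            for s in studies
            if confusion_from_study(s.record, key.risk_allele, unit) is not None
        ]
        n_cohorts_raw = len({s.record.cohort for s in with_raw})
        n_cohorts = len({s.record.cohort for s in studies})
        if n_cohorts_raw >= min_pooled:
            out.append(StratumEligibility(group.key, key, tuple(studies), True))
        elif n_cohorts < min_pooled:
            out.append(
                StratumEligibility(
                    group.key, key, tuple(studies), False,
                    IneligibilityReason.SINGLETON_STRATUM,
                )
            )
        else:
            out.append(
                StratumEligibility(
                    group.key, key, tuple(studies), False,
                    IneligibilityReason.NO_RAW_DATA,
                )
            )
    return out


def predictability_table(
    groups: Iterable[EvidenceGroup],
    min_pooled: int = 2,
    unit: Unit = Unit.ALLELE,
) -> list[PredictabilityResult]:
    """Pooled sensitivity/specificity/PPV for every eligible stratum.

    A variant with two concordant strata (opposite alleles, each replicated
    with raw data) yields two results.
    """
    results = []
    for g in groups:
        for el in eligible_strata(g, min_pooled=min_pooled, unit=unit):
            if not el.eligible:
                continue
            confusions = []
            n_case = n_ctrl = 0
            for s in el.studies:
                c = confusion_from_study(s.record, el.stratum.risk_allele, unit)
                if c is not None:
                    confusions.append(c)
                    n_case += s.record.n_case
                    n_ctrl += s.record.n_control
            pooled = pool(confusions)
            sens, spec, ppv = metrics(pooled)
            results.append(
                PredictabilityResult(
                    key=g.key,
                    variant=g.variant,
                    stratum=el.stratum,
                    sensitivity=sens,
                    specificity=spec,
                    ppv=ppv,
                    confusion=pooled,
                    n_studies_pooled=len(confusions),
                    n_case_total=n_case,
                    n_ctrl_total=n_ctrl,
                )
            )
    return results


def shortlist(
    groups: Sequence[EvidenceGroup],
    results: Sequence[PredictabilityResult],
    undetermined_is_inconsistent: bool = True,
) -> list[EvidenceGroup]:
    """Variants that are replicated, risk-allele consistent and PPV-computable.

    For treatment-response evidence the consistency requirement still spans
    all studies of the variant, while the computed PPV necessarily comes from
    a single (outcome, drug class) stratum.
    """
    from .replication import assess_consistency, Consistency

    with_ppv = {r.key for r in results}
    out = []
    for g in groups:
        status = assess_consistency(g, undetermined_is_inconsistent)
        if status.status is Consistency.CONSISTENT and g.key in with_ppv:
            out.append(g)
    return out
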