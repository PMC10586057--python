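"""Allelic association statistics and risk-allele harmonization.

Curated literature reports mix allelic and genotypic contrasts, protective and
risk orientations, and varying completeness of raw data.  This module reduces
each study to a common currency: an allelic 2x2 table (risk vs wild-type
allele counts in cases and controls), the allelic odds ratio with a Woolf
log-normal confidence interval, a Pearson chi-square allelic *P* value, and a
*harmonized* risk allele — the allele overrepresented in cases, obtained by
flipping reported protective associations (OR < 1) to the opposite allele.

Allelic association is preferred over genotypic whenever raw counts allow
recomputation; reported statistics are the fallback.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats as _sps

from .types import ReportedModel, StudyRecord, VariantKey, reverse_complement

Z_95 = 1.959964  # two-sided 95% normal quantile, fixed

ALPHA = 0.05


class TestMethod(str, enum.Enum):
    PEARSON = "pearson"  # chi-square, no continuity correction (default)
    YATES = "yates"  # chi-square with continuity correction
    FISHER = "fisher"  # Fisher's exact, two-sided


class Basis(str, enum.Enum):
    RAW_COUNTS = "raw_counts"
    RECONSTRUCTED_FREQS = "reconstructed_freqs"
    REPORTED_OR_DIRECTION = "reported_or_direction"
    REPORTED_GENOTYPE = "reported_genotype"
    REPORTED_ONLY = "reported_only"
    UNKNOWN = "unknown"


class UndefinedEstimateError(ValueError):
    """2x2 table degenerate for the requested statistic."""


@dataclass(frozen=True)
class AlleleTable2x2:
    """Allele-level 2x2 table: risk vs wild-type in cases vs controls."""

    case_risk: int
    case_wild: int
    ctrl_risk: int
    ctrl_wild: int

    def __post_init__(self) -> None:
        cells = (self.case_risk, self.case_wild, self.ctrl_risk, self.ctrl_wild)
        if any(c < 0 for c in cells):
            raise ValueError("allele counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    @property
    def n_case_alleles(self) -> int:
        return self.case_risk + self.case_wild

    @property
    def n_ctrl_alleles(self) -> int:
        return self.ctrl_risk + self.ctrl_wild

    def swapped_groups(self) -> "AlleleTable2x2":
        return AlleleTable2x2(
            self.ctrl_risk, self.ctrl_wild, self.case_risk, self.case_wild
        )


@dataclass(frozen=True)
class AssocResult:
    """Harmonized per-study association summary used downstream."""

    or_hat: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_allelic: Optional[float]
    risk_allele: Optional[str]
    significant: bool
    basis: Basis


def alleles_from_genotypes(
    gc: tuple[int, int, int, int, int, int],
) -> tuple[int, int, int, int]:
    """Collapse genotype counts (case AA/AB/BB, ctrl AA/AB/BB) to allele counts.

    Returns (case_a, case_b, ctrl_a, ctrl_b) with a = 2*AA + AB and
    b = 2*BB + AB per group.
    """
    if any(c < 0 for c in gc):
        raise ValueError("genotype counts must be non-negative")
    caa, cab, cbb, kaa, kab, kbb = gc
    if caa + cab + cbb == 0 or kaa + kab + kbb == 0:
        raise UndefinedEstimateError("a group has no genotyped subjects")
    return (2 * caa + cab, 2 * cbb + cab, 2 * kaa + kab, 2 * kbb + kab)


def allelic_odds_ratio(
    t: AlleleTable2x2, zero_cell_correction: float = 0.5
) -> tuple[float, float, float]:
    """Allelic odds ratio with a 95% Woolf (log-normal) interval.

    A Haldane–Anscombe correction (default +0.5 on all four cells) is applied
    when any cell is zero; it is applied for the OR/CI only, never to the
    counts used by the chi-square test.
    """
    cells = [t.case_risk, t.case_wild, t.ctrl_risk, t.ctrl_wild]
    if (t.case_risk + t.case_wild) == 0 or (t.ctrl_risk + t.ctrl_wild) == 0:
        raise UndefinedEstimateError("a group of the 2x2 table is empty")
    if any(c == 0 for c in cells):
        cells = [c + zero_cell_correction for c in cells]
    a, b, c, d = cells
    or_hat = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_hat)
    return (
        or_hat,
        math.exp(log_or - Z_95 * se),
        math.exp(log_or + Z_95 * se),
    )


def allelic_chi2_p(
    t: AlleleTable2x2, method: TestMethod = TestMethod.PEARSON
) -> float:
    """Allelic test *P* value for a 2x2 table.

    Default is the Pearson chi-square with 1 df and no continuity correction,
    the conventional "allelic P"; Yates correction and Fisher's exact test are
    available for small tables.
    """
    a, b, c, d = t.case_risk, t.case_wild, t.ctrl_risk, t.ctrl_wild
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedEstimateError("zero margin; allelic test undefined")
    if method is TestMethod.FISHER:
        return float(_sps.fisher_exact([[a, b], [c, d]])[1])
    n = r1 + r2
    delta = abs(a * d - b * c)
    if method is TestMethod.YATES:
        delta = max(delta - n / 2, 0.0)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    return float(_sps.chi2.sf(chi2, df=1))


def _normalize_reported_allele(
    variant: VariantKey, reported: str
) -> Optional[str]:
    """Map a reported allele onto the variant's allele pair.

    Literature reports occasionally use the opposite DNA strand; for SNVs the
    reverse complement is accepted, unless the variant is strand-ambiguous
    (A/T or C/G), where complement matching would be ill-defined.
    """
    if reported in variant.alleles:
        return reported
    pair = {variant.allele_a.upper(), variant.allele_b.upper()}
    ambiguous = pair in ({"A", "T"}, {"C", "G"})
    if not ambiguous:
        rc = reverse_complement(reported)
        if rc in variant.alleles:
            return rc
    return None


def allele_table_for_study(
    s: StudyRecord, risk_allele: str
) -> Optional[AlleleTable2x2]:
    """Build the allelic 2x2 table of a study oriented on ``risk_allele``.

    Preference order for raw data: allele counts, genotype counts, then allele
    frequencies (counts reconstructed as round(freq * 2n), half-up).  Returns
    None when the record has no usable raw data or the risk allele is not one
    of the variant's alleles.
    """
    if risk_allele not in s.variant.alleles:
        return None
    risk_is_b = risk_allele == s.variant.allele_b
    if s.allele_counts is not None:
        ca, cb, ka, kb = s.allele_counts
    elif s.genotype_counts is not None:
        ca, cb, ka, kb = alleles_from_genotypes(s.genotype_counts)
    elif s.case_freq_b is not None and s.ctrl_freq_b is not None:
        cb = _round_half_up(s.case_freq_b * 2 * s.n_case)
        kb = _round_half_up(s.ctrl_freq_b * 2 * s.n_control)
        ca, ka = 2 * s.n_case - cb, 2 * s.n_control - kb
    else:
        return None
    if risk_is_b:
        table = AlleleTable2x2(cb, ca, kb, ka)
    else:
        table = AlleleTable2x2(ca, cb, ka, kb)
    if s.directionality.value == "inverted":
        table = table.swapped_groups()
    return table


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def harmonize_risk_allele(s: StudyRecord) -> tuple[Optional[str], Basis]:
    """Harmonized risk allele of one study and the basis of the call.

    Raw counts dominate: the risk allele is the allele with the higher
    frequency in cases (an exact tie yields None).  Without raw data the
    reported allele is used, flipped to the opposite allele when the reported
    OR is protective (< 1); a genotype-only report contributes the allele
    composing the reported risk genotype.  No direction inferable -> (None,
    UNKNOWN), never an exception.
    """
    if s.has_raw_counts:
        table = allele_table_for_study(s, s.variant.allele_b)
        if table is not None:
            f_case = table.case_risk / table.n_case_alleles
            f_ctrl = table.ctrl_risk / table.n_ctrl_alleles
            if f_case > f_ctrl:
                return s.variant.allele_b, Basis.RAW_COUNTS
            if f_case < f_ctrl:
                return s.variant.allele_a, Basis.RAW_COUNTS
            return None, Basis.RAW_COUNTS
    reported = s.reported_risk_allele
    if reported:
        allele = _normalize_reported_allele(s.variant, reported)
        if allele is None:
            return None, Basis.UNKNOWN
        basis = (
            Basis.REPORTED_GENOTYPE
            if s.reported_model is ReportedModel.GENOTYPIC
            else Basis.REPORTED_OR_DIRECTION
        )
        if s.or_value is not None and s.or_value < 1:
            return s.variant.other_allele(allele), basis
        # OR > 1 or absent: the reported allele is taken at face value as
        # the risk allele (the curated column is a risk-allele column).
        return allele, basis
    return None, Basis.UNKNOWN


def select_reported_association(
    s: StudyRecord,
    alpha: float = ALPHA,
    method: TestMethod = TestMethod.PEARSON,
) -> Optional[AssocResult]:
    """Single association summary for a study, preferring recomputation.

    When raw counts exist the allelic OR/CI/*P* are recomputed from them and
    override any reported (possibly genotypic) statistics; otherwise the
    reported OR/CI/*P* are carried through.  Returns None for a record with
    neither raw data nor a reported *P* value (unassessable; callers exclude
    and log it).
    """
    risk, basis = harmonize_risk_allele(s)
    if s.has_raw_counts and risk is not None:
        table = allele_table_for_study(s, risk)
        if table is not None:
            raw_basis = (
                Basis.RECONSTRUCTED_FREQS
                if s.allele_counts is None and s.genotype_counts is None
                else Basis.RAW_COUNTS
            )
            try:
                or_hat, lo, hi = allelic_odds_ratio(table)
                p = allelic_chi2_p(table, method=method)
            except UndefinedEstimateError:
                or_hat = lo = hi = p = None
            if p is not None:
                return AssocResult(
                    or_hat, lo, hi, p, risk, p < alpha, raw_basis
                )
    if s.p_value is None:
        return None
    return AssocResult(
        s.or_value,
        s.ci_low,
        s.ci_high,
        s.p_value,
        risk,
        s.p_value < alpha,
        basis if risk is not None else Basis.REPORTED_ONLY,
    )
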