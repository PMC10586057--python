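"""Synthetic study catalogs with known ground truth.

Each synthetic variant has a control risk-allele frequency ``p0`` and a true
allelic odds ratio ``psi``; the implied case frequency is

    p1 = psi * p0 / (1 + p0 * (psi - 1)),

i.e. odds(p1) = psi * odds(p0).  Per study, case risk-allele counts are drawn
Binomial(2*n_case, p1) and control counts Binomial(2*n_control, p0) —
Hardy–Weinberg at the allele level; genotype counts, when requested, are
multinomial under HWE so carrier-unit analyses are exercised too.  Reporting
pathologies of the curated literature are emulated by two rates: a study may
*flip* its reported risk allele (raw counts untouched) or *withhold* raw
counts entirely, making it ineligible for predictability pooling.

Randomness is driven by a single integer seed through per-(variant, study)
substreams, so insertion order never changes results and a fixed seed
reproduces the catalog byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import stats
from .types import (
    Catalog,
    Design,
    Domain,
    ReportedModel,
    StudyRecord,
    VariantKey,
)


class TruthParams(BaseModel):
    """Ground-truth parameters for one synthetic variant."""

    model_config = ConfigDict(frozen=True)

    p0: float
    psi: float
    n_case: int = 1000
    n_control: int = 1000
    n_studies: int = 5
    discordance_rate: float = 0.0
    missing_raw_rate: float = 0.0
    design_mix: float = 0.0  # fraction of studies labelled GWAS
    genotypes: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TruthParams":
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie strictly inside (0, 1)")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        for name in ("discordance_rate", "missing_raw_rate", "design_mix"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_case <= 0 or self.n_control <= 0 or self.n_studies <= 0:
            raise ValueError("sizes must be positive")
        return self

    @property
    def p1(self) -> float:
        return case_freq_from_or(self.p0, self.psi)


def case_freq_from_or(p0: float, psi: float) -> float:
    """Case risk-allele frequency implied by control frequency and allelic OR.

    The unique p1 with odds(p1) = psi * odds(p0).
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if psi <= 0:
        raise ValueError("psi must be positive")
    return psi * p0 / (1 + p0 * (psi - 1))


def _rng_for(seed: int, variant_id: str, study_index: int) -> np.random.Generator:
    """Substream keyed by (seed, variant, study): order-independent."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(variant_id.encode()), study_index]
    )


def _default_variant(variant_id: str, index: int) -> VariantKey:
    return VariantKey(
        variant_id=variant_id,
        gene=f"GENE{index + 1}",
        chrom="1",
        pos=1000 + index,
        allele_a="A",
        allele_b="G",
    )


def simulate_study(
    t: TruthParams,
    study_index: int,
    variant: Optional[VariantKey] = None,
    variant_index: int = 0,
) -> StudyRecord:
    """Simulate one case-control study record for a synthetic variant.

    allele_b is the risk allele when psi > 1.  The record's reported OR/CI/P
    and risk allele are self-computed from the drawn counts (the 'honest'
    report), then reporting pathologies are applied: with probability
    ``discordance_rate`` the *reported* allele is flipped, and with
    probability ``missing_raw_rate`` the raw counts are withheld.
    """
    variant = variant or _default_variant(f"sv{variant_index + 1}", variant_index)
    rng = _rng_for(t.seed, variant.variant_id, study_index)
    n_case, n_ctrl = t.n_case, t.n_control
    if t.genotypes:
        p1, p0 = t.p1, t.p0

        def draw_genotypes(n: int, p: float) -> tuple[int, int, int]:
            probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]  # AA, AB, BB under HWE
            aa, ab, bb = rng.multinomial(n, probs)
            return int(aa), int(ab), int(bb)

        cg = draw_genotypes(n_case, p1)
        kg = draw_genotypes(n_ctrl, p0)
        gc: Optional[tuple] = cg + kg
        cb = 2 * cg[2] + cg[1]
        kb = 2 * kg[2] + kg[1]
        ac = None
    else:
        cb = int(rng.binomial(2 * n_case, t.p1))
        kb = int(rng.binomial(2 * n_ctrl, t.p0))
        gc = None
        ac = (2 * n_case - cb, cb, 2 * n_ctrl - kb, kb)
    table = stats.AlleleTable2x2(cb, 2 * n_case - cb, kb, 2 * n_ctrl - kb)
    or_hat, lo, hi = stats.allelic_odds_ratio(table)
    p = stats.allelic_chi2_p(table)
    risk = variant.allele_b if or_hat >= 1 else variant.allele_a
    if rng.random() < t.discordance_rate:
        risk = variant.other_allele(risk)
    missing_raw = rng.random() < t.missing_raw_rate
    design = Design.GWAS if rng.random() < t.design_mix else Design.CANDIDATE
    pooled_b = (cb + kb) / (2 * (n_case + n_ctrl))
    maf = min(pooled_b, 1 - pooled_b)
    return StudyRecord(
        pub_id=f"{variant.variant_id}_study{study_index + 1}",
        variant=variant,
        design=design,
        domain=Domain.SUSCEPTIBILITY,
        population="synthetic",
        n_case=n_case,
        n_control=n_ctrl,
        genotype_counts=None if missing_raw else gc,
        allele_counts=None if missing_raw else ac,
        reported_risk_allele=risk,
        reported_model=ReportedModel.ALLELIC,
        or_value=round(or_hat, 6),
        ci_low=round(min(lo, or_hat), 6),
        ci_high=round(max(hi, or_hat), 6),
        p_value=max(min(p, 1.0), 1e-300),
        maf_study=round(maf, 6),
        maf_global=round(maf, 6),
        raw_data_available=not missing_raw,
    )


def generate_catalog(
    params: Sequence[TruthParams],
    n_null_variants: int = 0,
    seed: Optional[int] = None,
) -> tuple[Catalog, list[dict]]:
    """Generate a catalog spanning variants x studies plus a truth table.

    ``params`` gives one TruthParams per signal variant; ``n_null_variants``
    appends psi = 1 decoys cloned from the first entry.  ``seed`` overrides
    the per-entry seeds so one integer drives the whole catalog.  Returns the
    catalog and a truth table (variant_id, p0, psi, p1) for recovery tests.
    """
    if not params and n_null_variants == 0:
        raise ValueError("at least one variant spec is required")
    specs = list(params)
    if n_null_variants:
        base = specs[0] if specs else TruthParams(p0=0.3, psi=1.0)
        specs += [replace_psi(base, 1.0)] * n_null_variants
    records, truth = [], []
    for vi, t in enumerate(specs):
        if seed is not None:
            t = t.model_copy(update={"seed": int(seed)})
        variant = _default_variant(f"sv{vi + 1}", vi)
        truth.append(
            {"variant_id": variant.variant_id, "p0": t.p0, "psi": t.psi, "p1": t.p1}
        )
        for si in range(t.n_studies):
            records.append(
                simulate_study(t, si, variant=variant, variant_index=vi)
            )
    return Catalog(records=records, source="synthetic"), truth


def replace_psi(t: TruthParams, psi: float) -> TruthParams:
    return t.model_copy(update={"psi": psi})


def write_truth_table(truth: list[dict], path) -> None:
    """Write the truth TSV (variant_id, p0, psi, p1)."""
    lines = ["variant_id\tp0\tpsi\tp1"]
    for row in truth:
        lines.append(
            f"{row['variant_id']}\t{row['p0']!r}\t{row['psi']!r}\t{row['p1']!r}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
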