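"""Catalog and annotation table IO.

The catalog is a tab-separated file, one row per published association
result, with the literal string ``NA`` for absent optional fields (zeros are
never used for missing).  Bundled fixtures transcribe the replicated-variant
and replicated-gene tables of the MDD susceptibility / antidepressant
response evidence base; per-study allele counts in the variant fixtures are
synthetic reconstructions (the underlying per-study frequencies are published
only in supplementary material) constrained to preserve each study's reported
risk-allele direction and significance — see ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from pydantic import ValidationError

from .types import (
    AnnotationRecord,
    Catalog,
    Design,
    Directionality,
    Domain,
    DrugClass,
    PolyphenClass,
    RegulomeCategory,
    ReportedModel,
    SiftClass,
    StudyRecord,
    VariantClass,
    VariantKey,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

CATALOG_COLUMNS = [
    "pub_id", "cohort_id", "variant_id", "gene", "chrom", "pos",
    "allele_a", "allele_b", "variant_class", "design", "domain",
    "drug_class", "outcome_scale", "population", "n_case", "n_control",
    "directionality",
    "case_AA", "case_AB", "case_BB", "ctrl_AA", "ctrl_AB", "ctrl_BB",
    "case_a", "case_b", "ctrl_a", "ctrl_b",
    "case_freq_b", "ctrl_freq_b",
    "reported_risk_allele", "reported_model",
    "or_value", "ci_low", "ci_high", "p_value",
    "maf_study", "maf_global", "raw_data_available",
]

ANNOTATION_COLUMNS = [
    "variant_id", "missense_flag", "sift_class", "polyphen_class",
    "regulome_rank", "splice_flag", "mirna_flag", "conservation",
    "reg_potential", "ko_mouse", "drug_target", "brain_expressed",
]

FIXTURE_NAMES = {
    "mdd_variants": "mdd_variants.tsv",
    "mdd_genes": "mdd_genes.tsv",
    "response_variants": "response_variants.tsv",
    "response_genes": "response_genes.tsv",
}

ANNOTATION_FIXTURE_NAMES = {
    "annotations_mdd": "annotations_mdd.tsv",
    "annotations_response": "annotations_response.tsv",
    "shortlist_annotations": "shortlist_annotations.tsv",
}

NA = "NA"


class SchemaError(ValueError):
    """Input file does not match the catalog schema."""


class CatalogValidationError(ValueError):
    """A row violates a record invariant."""


def _na(value) -> Optional[str]:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", NA, "nan"):
        return None
    return s


def _parse_num(value, row: int, column: str, kind=float):
    s = _na(value)
    if s is None:
        return None
    try:
        return kind(float(s)) if kind is int else kind(s)
    except (TypeError, ValueError) as exc:
        raise SchemaError(
            f"row {row}: cannot parse {column}={value!r} as {kind.__name__}"
        ) from exc


def _parse_bool(value, row: int, column: str) -> Optional[bool]:
    s = _na(value)
    if s is None:
        return None
    low = s.lower()
    if low in ("true", "t", "1", "y", "yes"):
        return True
    if low in ("false", "f", "0", "n", "no"):
        return False
    raise SchemaError(f"row {row}: cannot parse {column}={value!r} as boolean")


def _record_from_row(row: pd.Series, idx: int) -> StudyRecord:
    variant = VariantKey(
        variant_id=_na(row["variant_id"]) or "",
        gene=_na(row["gene"]) or "",
        chrom=_na(row["chrom"]),
        pos=_parse_num(row["pos"], idx, "pos", int),
        allele_a=_na(row["allele_a"]) or "",
        allele_b=_na(row["allele_b"]) or "",
        variant_class=VariantClass(_na(row["variant_class"]) or "SNV"),
    )
    gt_cells = [
        _parse_num(row[c], idx, c, int)
        for c in ("case_AA", "case_AB", "case_BB", "ctrl_AA", "ctrl_AB", "ctrl_BB")
    ]
    al_cells = [
        _parse_num(row[c], idx, c, int)
        for c in ("case_a", "case_b", "ctrl_a", "ctrl_b")
    ]
    gc = tuple(gt_cells) if all(v is not None for v in gt_cells) else None
    ac = tuple(al_cells) if all(v is not None for v in al_cells) else None
    drug = _na(row["drug_class"])
    return StudyRecord(
        pub_id=_na(row["pub_id"]) or "",
        cohort_id=_na(row["cohort_id"]),
        variant=variant,
        design=Design(_na(row["design"]) or ""),
        domain=Domain(_na(row["domain"]) or ""),
        drug_class=DrugClass(drug) if drug else None,
        outcome_scale=_na(row["outcome_scale"]),
        population=_na(row["population"]),
        n_case=_parse_num(row["n_case"], idx, "n_case", int) or 0,
        n_control=_parse_num(row["n_control"], idx, "n_control", int) or 0,
        directionality=Directionality(_na(row["directionality"]) or "standard"),
        genotype_counts=gc,
        allele_counts=ac,
        case_freq_b=_parse_num(row["case_freq_b"], idx, "case_freq_b"),
        ctrl_freq_b=_parse_num(row["ctrl_freq_b"], idx, "ctrl_freq_b"),
        reported_risk_allele=_na(row["reported_risk_allele"]),
        reported_model=ReportedModel(_na(row["reported_model"]) or "unknown"),
        or_value=_parse_num(row["or_value"], idx, "or_value"),
        ci_low=_parse_num(row["ci_low"], idx, "ci_low"),
        ci_high=_parse_num(row["ci_high"], idx, "ci_high"),
        p_value=_parse_num(row["p_value"], idx, "p_value"),
        maf_study=_parse_num(row["maf_study"], idx, "maf_study"),
        maf_global=_parse_num(row["maf_global"], idx, "maf_global"),
        raw_data_available=_parse_bool(
            row["raw_data_available"], idx, "raw_data_available"
        )
        or False,
    )


def read_catalog(
    path: Union[str, Path], schema_version: str = SCHEMA_VERSION
) -> Catalog:
    """Read and validate a catalog TSV.

    Raises :class:`SchemaError` for a missing column or unparseable number
    (naming the column / row) and :class:`CatalogValidationError` for an
    invariant violation (naming pub_id and field).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(_record_from_row(row, int(idx) + 2))
        except ValidationError as exc:
            pid = _na(row.get("pub_id")) or "?"
            raise CatalogValidationError(
                f"invalid record pub_id={pid} (row {int(idx) + 2}): {exc}"
            ) from exc
    return Catalog(records=records, source=str(path), schema_version=schema_version)


def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if hasattr(value, "value"):
        return str(value.value)
    return str(value)


def write_catalog(catalog: Catalog, path: Union[str, Path]) -> None:
    """Write a catalog as TSV, full numeric precision, NA for absent fields."""
    rows = []
    for rec in catalog.records:
        v = rec.variant
        gc = rec.genotype_counts or (None,) * 6
        ac = rec.allele_counts or (None,) * 4
        rows.append(
            {
                "pub_id": rec.pub_id,
                "cohort_id": rec.cohort_id,
                "variant_id": v.variant_id,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "allele_a": v.allele_a,
                "allele_b": v.allele_b,
                "variant_class": v.variant_class,
                "design": rec.design,
                "domain": rec.domain,
                "drug_class": rec.drug_class,
                "outcome_scale": rec.outcome_scale,
                "population": rec.population,
                "n_case": rec.n_case,
                "n_control": rec.n_control,
                "directionality": rec.directionality,
                "case_AA": gc[0], "case_AB": gc[1], "case_BB": gc[2],
                "ctrl_AA": gc[3], "ctrl_AB": gc[4], "ctrl_BB": gc[5],
                "case_a": ac[0], "case_b": ac[1],
                "ctrl_a": ac[2], "ctrl_b": ac[3],
                "case_freq_b": rec.case_freq_b,
                "ctrl_freq_b": rec.ctrl_freq_b,
                "reported_risk_allele": rec.reported_risk_allele,
                "reported_model": rec.reported_model,
                "or_value": rec.or_value,
                "ci_low": rec.ci_low,
                "ci_high": rec.ci_high,
                "p_value": rec.p_value,
                "maf_study": rec.maf_study,
                "maf_global": rec.maf_global,
                "raw_data_available": rec.raw_data_available,
            }
        )
    lines = ["\t".join(CATALOG_COLUMNS)]
    for row in rows:
        lines.append("\t".join(_fmt(row[c]) for c in CATALOG_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: Union[str, Path]) -> list[AnnotationRecord]:
    """Read an annotation TSV into validated records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for idx, row in df.iterrows():
        i = int(idx) + 2
        rank = _na(row["regulome_rank"])
        out.append(
            AnnotationRecord(
                variant_id=_na(row["variant_id"]) or "",
                missense_flag=_parse_bool(row["missense_flag"], i, "missense_flag")
                or False,
                sift_class=SiftClass(_na(row["sift_class"]) or "na"),
                polyphen_class=PolyphenClass(_na(row["polyphen_class"]) or "na"),
                regulome_rank=RegulomeCategory(rank.lower() if rank else "na"),
                splice_flag=_parse_bool(row["splice_flag"], i, "splice_flag")
                or False,
                mirna_flag=_parse_bool(row["mirna_flag"], i, "mirna_flag") or False,
                conservation=_parse_num(row["conservation"], i, "conservation"),
                reg_potential=_parse_num(row["reg_potential"], i, "reg_potential"),
                ko_mouse=_parse_bool(row["ko_mouse"], i, "ko_mouse"),
                drug_target=_parse_bool(row["drug_target"], i, "drug_target"),
                brain_expressed=_parse_bool(
                    row["brain_expressed"], i, "brain_expressed"
                ),
            )
        )
    return out


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("evsyn").joinpath("fixtures", filename)))


def load_fixture(name: str) -> Union[Catalog, list[AnnotationRecord]]:
    """Load a bundled fixture by name.

    Catalog fixtures: ``mdd_variants``, ``mdd_genes``, ``response_variants``,
    ``response_genes``.  Annotation fixtures: ``annotations_mdd``,
    ``annotations_response``, ``shortlist_annotations``.
    """
    if name in FIXTURE_NAMES:
        return read_catalog(_fixture_path(FIXTURE_NAMES[name]))
    if name in ANNOTATION_FIXTURE_NAMES:
        return read_annotations(_fixture_path(ANNOTATION_FIXTURE_NAMES[name]))
    known = sorted(FIXTURE_NAMES) + sorted(ANNOTATION_FIXTURE_NAMES)
    raise KeyError(f"unknown fixture {name!r}; known: {', '.join(known)}")


_VCF_HEADER = """##fileformat=VCFv4.3
##source=evsyn
##INFO=<ID=EVC,Number=1,Type=String,Description="Evidence class (candidate/gwas/both)">
##INFO=<ID=NST,Number=1,Type=Integer,Description="Number of supporting studies">
##INFO=<ID=RA,Number=1,Type=String,Description="Harmonized risk allele">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"""


def export_vcf(
    variants: Iterable[tuple[VariantKey, dict]],
    path: Union[str, Path],
) -> None:
    """Write a minimal VCFv4.3 of variants with evidence attributes.

    ``variants`` yields (key, attrs) where attrs may carry ``evidence_class``,
    ``n_studies`` and ``risk_allele``.  Non-SNV variants are written with a
    symbolic ALT and a warning; variants lacking coordinates are skipped (the
    skip count is logged).
    """
    lines = [_VCF_HEADER]
    skipped = 0
    for key, attrs in variants:
        if key.chrom is None or key.pos is None:
            skipped += 1
            continue
        if key.variant_class is not VariantClass.SNV:
            logger.warning(
                "non-SNV variant %s exported with symbolic ALT", key.variant_id
            )
            ref, alt = "N", f"<{key.variant_class.value.upper()}>"
        else:
            ref, alt = key.allele_a, key.allele_b
        info = ";".join(
            part
            for part in (
                f"EVC={attrs['evidence_class']}" if "evidence_class" in attrs else "",
                f"NST={attrs['n_studies']}" if "n_studies" in attrs else "",
                f"RA={attrs['risk_allele']}" if attrs.get("risk_allele") else "",
            )
            if part
        )
        lines.append(
            f"{key.chrom}\t{key.pos}\t{key.variant_id}\t{ref}\t{alt}\t.\t.\t{info or '.'}"
        )
    if skipped:
        logger.info("export_vcf: skipped %d variant(s) without coordinates", skipped)
    Path(path).write_text("\n".join(lines) + "\n")
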