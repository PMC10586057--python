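"""End-to-end pipeline: catalog -> replication -> predictability -> reports.

``run_pipeline`` executes the full evidence synthesis for one domain
(disease susceptibility or treatment response) and returns a report bundle:
the replicated-variant table with buckets and consistency, the gene-level
table, the predictability table, the shortlist, an optional annotation
summary, and a machine-readable summary dictionary whose every count is
recomputable from the emitted tables (verified at the end of each run).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import annotation as annot_mod
from . import catalog as catalog_mod
from . import predictability as pred_mod
from . import replication as repl_mod
from .predictability import PredictabilityResult, Unit
from .replication import Consistency, EvidenceGroup, Level
from .stats import TestMethod
from .types import AnnotationRecord, Catalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of one pipeline run."""

    domain: str = "mdd"  # 'mdd' or 'response'
    min_studies: int = 2
    maf_threshold: float = 0.05
    unit: Unit = Unit.ALLELE
    min_pooled: int = 2
    alpha: float = 0.05
    test_method: TestMethod = TestMethod.PEARSON
    high_regulatory_below: int = 3
    undetermined_is_inconsistent: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must lie in (0, 0.5]")
        if self.min_studies < 1 or self.min_pooled < 1:
            raise ValueError("min_studies and min_pooled must be >= 1")


@dataclass
class ReportBundle:
    config: PipelineConfig
    variant_groups: list[EvidenceGroup]
    maf_excluded: list[EvidenceGroup]
    gene_groups: list[EvidenceGroup] = field(default_factory=list)
    results: list[PredictabilityResult] = field(default_factory=list)
    shortlisted: list[EvidenceGroup] = field(default_factory=list)
    annotation_summary: Optional[annot_mod.AnnotationSummary] = None
    summary: dict = field(default_factory=dict)


def run_pipeline(
    catalog: Catalog,
    config: PipelineConfig = PipelineConfig(),
    gene_catalog: Optional[Catalog] = None,
    annotations: Optional[Sequence[AnnotationRecord]] = None,
) -> ReportBundle:
    """Run replication, consistency, predictability and annotation summary.

    ``gene_catalog`` (the replicated-gene evidence table, which includes
    studies below the per-variant level) feeds gene-level bucket counts; when
    omitted, gene grouping falls back to the variant catalog's gene column.
    """
    cfg = config
    groups = repl_mod.group_records(
        catalog, Level.VARIANT, cfg.domain, alpha=cfg.alpha, method=cfg.test_method
    )
    replicated = repl_mod.filter_replicated(groups, cfg.min_studies)
    kept, excluded = repl_mod.filter_maf(replicated, cfg.maf_threshold)
    bucket_counts = repl_mod.bucket_counts(kept)
    tally = repl_mod.consistency_tally(kept, cfg.undetermined_is_inconsistent)

    gene_src = gene_catalog if gene_catalog is not None else catalog
    gene_groups = repl_mod.filter_replicated(
        repl_mod.group_records(
            gene_src, Level.GENE, cfg.domain, alpha=cfg.alpha, method=cfg.test_method
        ),
        cfg.min_studies,
    )
    gene_bucket_counts = repl_mod.bucket_counts(gene_groups)

    results = pred_mod.predictability_table(
        kept, min_pooled=cfg.min_pooled, unit=cfg.unit
    )
    shortlisted = pred_mod.shortlist(
        kept, results, cfg.undetermined_is_inconsistent
    )
    ppvs = [r.ppv for r in results]

    ann_summary = None
    if annotations is not None:
        ann_summary = annot_mod.summarize(
            annotations,
            variants=[g.key for g in kept],
            high_regulatory_below=cfg.high_regulatory_below,
        )

    summary = {
        "domain": cfg.domain,
        "n_replicated_unique": len(kept),
        "buckets": {
            k: bucket_counts[k] for k in ("candidate", "gwas", "both")
        },
        "bucket_sum": bucket_counts["bucket_sum"],
        "maf_excluded": sorted(g.key for g in excluded),
        "consistency": tally,
        "gene_buckets": {
            k: gene_bucket_counts[k] for k in ("candidate", "gwas", "both")
        },
        "n_genes_replicated_unique": gene_bucket_counts["unique"],
        "n_variants_with_ppv": len({r.key for r in results}),
        "ppv_min": min(ppvs) if ppvs else None,
        "ppv_max": max(ppvs) if ppvs else None,
        "shortlist": sorted(g.key for g in shortlisted),
    }
    bundle = ReportBundle(
        config=cfg,
        variant_groups=kept,
        maf_excluded=excluded,
        gene_groups=gene_groups,
        results=results,
        shortlisted=shortlisted,
        annotation_summary=ann_summary,
        summary=summary,
    )
    _check_internal_consistency(bundle)
    return bundle


def _check_internal_consistency(bundle: ReportBundle) -> None:
    """Every summary count must be recomputable from the bundle tables."""
    s = bundle.summary
    assert s["n_replicated_unique"] == len(bundle.variant_groups)
    assert s["bucket_sum"] == sum(s["buckets"].values())
    assert (
        s["consistency"]["consistent"] + s["consistency"]["inconsistent"]
        == s["bucket_sum"]
    )
    assert s["n_variants_with_ppv"] == len({r.key for r in bundle.results})
    assert set(s["shortlist"]) == {g.key for g in bundle.shortlisted}


# ---------------------------------------------------------------------------
# Rendering


def _metric_str(x: Optional[float]) -> str:
    return "NA" if x is None else f"{pred_mod.round_metric(x):.2f}"


def variant_table_rows(bundle: ReportBundle) -> list[dict]:
    rows = []
    for g in bundle.variant_groups:
        status = repl_mod.assess_consistency(
            g, bundle.config.undetermined_is_inconsistent
        )
        buckets = sorted(b.value for b in repl_mod.classify_evidence(g))
        rows.append(
            {
                "key": g.key,
                "n_studies": g.n_pubs,
                "n_countable": g.n_countable,
                "buckets": "+".join(buckets),
                "consistency": status.status.value,
                "modal_allele": status.modal_allele or "NA",
                "maf_global": g.maf_global if g.maf_global is not None else "NA",
            }
        )
    return rows


def predictability_rows(bundle: ReportBundle) -> list[dict]:
    rows = []
    for r in bundle.results:
        st = r.stratum
        rows.append(
            {
                "key": r.key,
                "risk_allele": st.risk_allele,
                "domain": st.domain.value if st.domain else "NA",
                "drug_class": st.drug_class.value if st.drug_class else "NA",
                "n_studies_pooled": r.n_studies_pooled,
                "sensitivity": _metric_str(r.sensitivity),
                "specificity": _metric_str(r.specificity),
                "ppv": _metric_str(r.ppv),
            }
        )
    return rows


def render_tables(
    rows: list[dict], out_base: Path, style: str = "tsv"
) -> list[Path]:
    """Render rows as TSV and/or markdown with a deterministic column order."""
    if style not in ("tsv", "markdown", "both"):
        raise ValueError("style must be 'tsv', 'markdown' or 'both'")
    paths = []
    columns = list(rows[0].keys()) if rows else []
    if style in ("tsv", "both"):
        p = out_base.with_suffix(".tsv")
        lines = ["\t".join(columns)]
        lines += ["\t".join(str(r[c]) for c in columns) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    if style in ("markdown", "both"):
        p = out_base.with_suffix(".md")
        if columns:
            lines = [
                "| " + " | ".join(columns) + " |",
                "| " + " | ".join("---" for _ in columns) + " |",
            ]
            lines += [
                "| " + " | ".join(str(r[c]) for c in columns) + " |" for r in rows
            ]
        else:
            lines = []
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths


def write_bundle(bundle: ReportBundle, out_dir: Path, style: str = "tsv") -> dict:
    """Write all report tables + summary JSON + manifest into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, rows in (
        ("variants", variant_table_rows(bundle)),
        ("predictability", predictability_rows(bundle)),
    ):
        for p in render_tables(rows, out_dir / name, style):
            written[p.name] = str(p)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(bundle.summary, indent=2, sort_keys=True) + "\n")
    written[summary_path.name] = str(summary_path)
    manifest = {
        "tool": "evsyn",
        "domain": bundle.config.domain,
        "parameters": {
            "min_studies": bundle.config.min_studies,
            "maf_threshold": bundle.config.maf_threshold,
            "unit": bundle.config.unit.value,
            "min_pooled": bundle.config.min_pooled,
            "alpha": bundle.config.alpha,
        },
        "outputs": sorted(written),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return written
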