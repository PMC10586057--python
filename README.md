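# evsyn

Evidence synthesis for the genetics of major depressive disorder (MDD) and
antidepressant treatment response.

Candidate-gene and GWAS case-control studies of MDD report association
results in wildly heterogeneous forms: allelic or genotypic contrasts, risk
or protective orientation, with or without raw allele frequencies. `evsyn`
turns a curated catalog of such per-study results into the quantities a
reviewer of this evidence base actually wants:

* **replication screening** — variants and genes significant (*P* < .05) in
  at least two independent cohorts, classified into *candidate*, *GWAS* and
  *both-design* evidence buckets, with a strict minor-allele-frequency
  filter (global MAF < 0.05 excluded);
* **risk-allele harmonization** — each study's reported association is
  reduced to a single harmonized risk allele: recomputed from raw counts
  when available (allele with the higher case frequency), otherwise the
  reported allele flipped to its opposite when the reported odds ratio is
  protective (OR < 1), and groups are classified as risk-allele
  *consistent* or *inconsistent*;
* **allelic statistics from raw counts** — allelic odds ratio
  OR = (a·d)/(b·c) with a 95% Woolf log-normal interval
  (SE = sqrt(1/a+1/b+1/c+1/d), z = 1.959964, Haldane–Anscombe +0.5 for zero
  cells) and the Pearson chi-square allelic *P* (1 df, no continuity
  correction; Yates and Fisher variants available);
* **pooled diagnostic predictability** — treating risk-allele carriage as a
  diagnostic test, studies that agree on the risk allele (and, for drug
  response, on outcome and drug class) are pooled by summing allele-level
  confusion tables, giving

      sensitivity = ΣTP / (ΣTP + ΣFN)
      specificity = ΣTN / (ΣTN + ΣFP)
      PPV         = ΣTP / (ΣTP + ΣFP)

  where TP/FN are risk/wild-type alleles in cases and FP/TN in controls;
* **a diagnostic shortlist** — variants that are replicated, risk-allele
  consistent across all studies, and have at least one computable pooled
  PPV;
* **functional-annotation summaries** over static SIFT / PolyPhen-2 /
  RegulomeDB / conservation / knockout-mouse / drug-target /
  brain-expression tables;
* **a synthetic-catalog generator** with known ground truth (control
  frequency p0, allelic OR ψ, implied case frequency
  p1 = ψp0/(1 + p0(ψ−1)), discordant-reporting and missing-raw-data rates)
  so every pipeline stage is testable without external data.

Bundled fixtures transcribe the replicated-variant and replicated-gene
evidence tables of the MDD / antidepressant-response literature (study
design, sample sizes, reported alleles, odds ratios, *P* values,
availability of raw data). Per-study allele counts inside those fixtures are
**synthetic reconstructions** constrained to preserve each study's reported
direction and significance — the true per-study frequencies exist only in
supplementary material; see `docs/methods.md`.

## Worked example

```sh
evsyn report --fixture mdd_variants --gene-fixture mdd_genes \
      --annotations-fixture annotations_mdd --domain mdd --out mdd_run
```

prints (abridged):

```json
{
  "bucket_sum": 31,
  "buckets": {"both": 4, "candidate": 24, "gwas": 3},
  "consistency": {"consistent": 13, "inconsistent": 18},
  "gene_buckets": {"both": 7, "candidate": 27, "gwas": 8},
  "maf_excluded": ["rs120074175", "rs6189+rs6190", "rs6195"],
  "n_replicated_unique": 30,
  "n_variants_with_ppv": 19,
  "shortlist": ["rs1006737", "rs1801131", "rs1801133", "rs242939",
                "rs4880", "rs5443", "rs6295"]
}
```

Reading: 30 unique MDD variants survive replication and the MAF filter
(three low-frequency variants are excluded); by evidence bucket they count
24 candidate + 3 GWAS + 4 both-design listings (31, one variant occupying
two buckets); 13 listings agree on a single harmonized risk allele and 18 do
not; 19 variants have at least one concordant stratum with raw data, hence a
pooled PPV; and 7 variants satisfy all three shortlist conditions. The
`predictability.tsv` table in the output directory holds one row per pooled
stratum, e.g.

```
key       risk_allele  n_studies_pooled  sensitivity  specificity  ppv
5-HTTLPR  S            6                 0.54         0.57         0.43
5-HTTLPR  L            3                 0.36         0.69         0.56
```

(two rows for one variant: its studies split into S-allele and L-allele
reporting camps, pooled separately). The same pipeline runs on the drug
response catalog with `--fixture response_variants --domain response`, where
pooling additionally respects outcome (response / remission / resistance)
and drug-class boundaries.

Synthetic data with known truth:

```sh
evsyn simulate --p0 0.30 --psi 1.5 --n-studies 5 --seed 17 --out sim_run
```

writes a catalog plus a `truth.tsv` of (p0, ψ, p1) for parameter-recovery
checks; pooled sensitivity estimates p1 and specificity 1−p0.

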