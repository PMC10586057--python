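# Methods

## The evidence model

The unit of evidence is one published case-control association result for
one polymorphism (`StudyRecord`): study design (candidate vs GWAS),
phenotype domain (disease susceptibility, or the treatment-outcome family:
response / remission / resistance), group sizes, raw data when reported
(genotype counts, allele counts, or allele frequencies), the reported risk
allele or genotype, odds ratio with confidence interval, unadjusted *P*
value, and study/global minor allele frequencies. Alleles are opaque
strings, so the serotonin-transporter promoter indel (L/S) and intron-2 VNTR
sit in the same catalog as rsID SNVs. For treatment-outcome studies the
"case" arm is the non-responder / non-remitter group (the group the risk
allele is overrepresented in); a `directionality` flag allows records whose
printed group order is inverted.

## Per-study reduction

Every record is reduced to one allelic association summary:

1. **Raw counts first.** If the study has usable raw data, genotype counts
   are collapsed to allele counts (a = 2AA + AB, b = 2BB + AB), frequencies
   are converted to counts by round-half-up of freq × 2n, and the allelic
   OR, 95% Woolf interval and Pearson chi-square *P* (1 df, no continuity
   correction) are recomputed, overriding any reported — possibly genotypic
   — statistics. This mirrors the curation convention of preferring allelic
   over genotypic association and recomputing from raw data.
2. **Reported statistics as fallback.** Without raw data the reported OR/CI
   and *P* are carried through.
3. **Harmonized risk allele.** From raw counts: the allele with the higher
   case frequency (exact tie → none). From a report: the reported allele,
   flipped to the opposite allele when the reported OR < 1. Reported alleles
   are normalized onto the variant's allele pair, accepting the reverse
   complement for SNVs (curated tables occasionally report the opposite
   strand), except for strand-ambiguous A/T and C/G variants. A genotype
   label contributes its composing allele with an explicit
   `reported_genotype` basis, recording the attribution uncertainty rather
   than guessing.
4. **Significance** is strict *P* < .05, unadjusted. GWAS records are
   admitted at their reported significance (including sub-genome-wide,
   "suggestive" *P* values), because the curated evidence tables do.

Numerical choices: z is fixed at 1.959964; zero cells get a
Haldane–Anscombe +0.5 on all four cells for the OR/CI only, never for the
chi-square counts; a zero-margin table raises an undefined-test error.
Yates-corrected chi-square and Fisher's exact test are available behind a
method switch for small tables.

## Replication, buckets, consistency

A variant (or gene) is **replicated** when significant in ≥ 2 independent
cohorts. The countable unit is the unique `cohort_id` (defaulting to the
publication id): multiple strata of one publication count once, and two
publications re-analysing one participant cohort count once. The displayed
study count remains the publication count, matching how the curated tables
bracket their totals.

Replicated variants with global MAF strictly below 0.05 are excluded
(= 0.05 is kept, following the stated "< 0.05" rule); a missing global MAF
keeps the group with a warning, which is how the VNTR without a reference
panel frequency survives.

**Evidence buckets** allow overlap: candidate (≥ 2 candidate cohorts), GWAS
(≥ 2 GWAS cohorts), both (≥ 1 of each). Headline counts are bucket sizes
summed over listings — a variant with two candidate studies plus one GWAS
study appears under both "candidate" and "both", exactly as the published
tables double-list such variants — and the deduplicated unique count is
reported alongside (24 + 3 + 4 = 31 listings over 30 unique MDD variants).

**Consistency** is tallied at the same listing level: a candidate listing is
judged over its candidate studies, a GWAS listing over its GWAS studies, a
both listing over all studies. A listing is consistent when every study
carries the same harmonized risk allele; a study with no inferable direction
counts as inconsistent for headline tallies (configurable). This is the
accounting under which 13 consistent + 18 inconsistent = 31; the
variant-level split over the 30 unique keys (13/17) is also computed and
reported by `assess_consistency`.

## Diagnostic predictability

Risk-allele carriage is treated as a diagnostic test. In the default
*allele* unit each subject contributes two alleles: TP = risk alleles in
cases, FN = wild-type alleles in cases, FP/TN the converse in controls (the
allele frequencies are the extracted raw datum, which is why the allele unit
is the default; a *carrier* unit counting subjects with ≥ 1 risk allele is
available when genotype counts exist). Studies pool by element-wise
summation of confusion tables — no inverse-variance weighting, matching the
Σ-definitions of the pooled metrics — within a stratum that fixes the
harmonized risk allele and, for treatment outcome, the (outcome domain, drug
class) pair; pooling never crosses those boundaries. A stratum is eligible
when ≥ 2 cohorts in it have raw data (`min_pooled`, configurable); smaller
or raw-less strata carry machine-readable ineligibility reasons. A variant
with two concordant strata (opposite alleles, each replicated with raw data)
yields two results. Metrics are kept unrounded; display rounding is two
decimals, half-up.

The **shortlist** keeps variants that are (a) replicated, (b) risk-allele
consistent across *all* their studies, and (c) have ≥ 1 computed PPV; for
drug response the PPV necessarily comes from a single outcome/drug-class
stratum while (b) still spans the whole variant.

## Fixtures and the reconstruction of study counts

The bundled fixtures transcribe the published evidence tables: per-study
design, sizes, population, reported risk allele/genotype, OR, CI, *P*,
global MAF and whether raw data were available ("–" cells). Three
low-frequency variants excluded from the published variant table are present
as minimal identity-level records so the MAF filter has something to remove.

The per-study **allele counts are synthetic reconstructions**, because the
true per-study frequencies are published only in supplementary tables. For
each stratum with printed pooled sensitivity/specificity, every raw-data
study receives control risk-allele frequency q0 = 1 − specificity and case
frequency q1 = sensitivity, provided q1 > q0 is compatible with the
per-study reports; otherwise the study is anchored on its own reported OR
(q0 = 0.30). q1 is then escalated in ×1.15 odds steps until the rounded 2×2
is individually significant with the case frequency strictly higher. The
reconstruction therefore preserves exactly the properties that drive every
headline count — each study's direction and significance, the stratum
structure, raw-data availability — and the pooled specificity of
spec-anchored strata by construction, while per-study magnitudes are not
data. Consequently:

* replication counts, bucket sizes, MAF exclusions, consistency tallies,
  eligibility counts and the shortlist are genuine recomputations;
* pooled sensitivities/specificities of anchored strata reproduce the
  printed values as a *consistency check of the pooling arithmetic*, not as
  independent validation;
* pooled PPVs are not expected to match the printed ones. Indeed the
  Σ-formula PPV = ΣTP/(ΣTP + ΣFP) applied to the printed stratum
  frequencies and the printed case/control totals gives ≈ 0.65 for the top
  MDD stratum (CRHR1 rs242939, G) against a printed 0.66 — and far smaller
  values for strata with large control excesses — so the published PPV
  column cannot be reproduced from the published table alone. The test
  asserting the printed maximum is left failing rather than retuned.

Annotation fixtures encode the per-variant SIFT/PolyPhen classes, RegulomeDB
ranks, splice/miRNA flags, conservation and regulatory-potential scores and
knockout-mouse/drug-target/brain-expression flags stated for individual
variants, filled deterministically for the remainder so that the published
summary counts hold over the fixture (e.g. 25 of the MDD variants with a
rank of 5 or stronger; the prose's "1 deleterious + 7 tolerated of 7
missense" is arithmetically impossible and is encoded as 1 + 5 of 6). The
"high regulatory" tier defaults to a leading rank digit < 3; the published
prose once draws the line to include a 3a variant, so the threshold is a
parameter rather than silently resolved.

## Synthetic data

The generator emulates the statistical structure the predictability analysis
assumes: per variant, a control risk-allele frequency p0 and true allelic OR
ψ give p1 = ψp0/(1 + p0(ψ − 1)); case allele counts are
Binomial(2n_case, p1) and control counts Binomial(2n_ctrl, p0) —
Hardy–Weinberg at the allele level — with optional multinomial genotypes
under HWE for the carrier unit. Reporting pathologies are two independent
per-study rates: flipping the *reported* risk allele (raw counts untouched)
and withholding raw counts. A single integer seed drives per-(variant,
study) substreams, so insertion order never changes results and reruns are
byte-identical. The generator deliberately omits population stratification,
LD between variants, covariates and GWAS-scale variant counts: passing
recovery tests shows the pipeline arithmetic is right under the model's own
assumptions, not that real catalogs are this well behaved.

Default study conditions used by the tests: n = 2000 per arm × 5 studies for
parameter recovery (pooled sensitivity within 3 Monte-Carlo SEs of p1),
2000 simulated null studies of 1000 per arm for type-I calibration
(0.05 ± 0.01), 200 studies for median-OR recovery within 5%, and 150 null
decoy variants for the replication false-positive rate against the binomial
tail. These sizes make the whole suite run in seconds while keeping the
Monte-Carlo error far below the tested tolerances.

## Known limitations

* The catalog model assumes curated allele orientations are consistent; no
  systematic strand resolution or liftover is attempted.
* Pooling is unweighted summation by design; no random-effects
  meta-analysis, NPV, likelihood ratios or interval estimates for
  sensitivity/specificity are provided.
* Gene-level grouping unions all variants in a gene and counts unique
  cohorts; it does not collapse variants in linkage disequilibrium.
* Fixture study counts are reconstructions (above); any analysis of the
  fixtures beyond the reproduced headline counts inherits that caveat.
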