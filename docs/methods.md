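# Methods

This note documents the models, rules and numerical choices behind
`cnstriage`, in the order the cascade runs them, followed by the
synthetic-data model, the packaged fixture, and known limitations.

## Diagnostic cascade

Samples are screened in three stages, and a sample's diagnostic stage is
the first stage that yields a *primary* finding (a pathogenic or likely
pathogenic variant judged relevant to the fetal imaging phenotype). The
cascade is exclusive by construction: a sample diagnosed at the low-pass
stage never has its small variants interpreted, and small-CNV assessment
runs only after uninformative SNV triage. This mirrors the two-stage
sequencing economics the design assumes — deep sequencing is only spent on
samples the shallow screen cannot resolve.

### Stage 1: low-pass read-depth screen

**GC correction.** Bin counts are normalised by the median autosomal count
within the bin's GC stratum (deciles of autosomal GC content), then
rescaled so the genome-wide autosomal median ratio is exactly 1. The
correction always recomputes from raw counts, making it idempotent. It
requires ≥ 50 autosomal bins. Quantile strata degrade gracefully to a
single stratum when GC is nearly constant.

**QC gate.** Profiles whose autosomal normalised ratios have a robust
dispersion (scaled MAD) above 0.25 are marked "CNV calling failed" —
a stand-in for the turbulent-read-depth failures such screens report; the
genuine failure rule is not published, so the gate is a deliberate,
configurable approximation. Failed samples keep their SNV analyses.

**Aneuploidy calling.** Per chromosome, z = (median ratio − reference) /
spread, where the spread is the scaled MAD of autosomal per-chromosome
medians *floored by the chromosome's own median sampling error*
(1.2533·MAD(bin ratios)/√n_bins). The floor exists because small
chromosomes have noisier medians than the cross-chromosome spread
suggests; without it, a 24-chromosome genome examined across many samples
accumulates false whole-chromosome calls. A call additionally requires the
median to move ≥ 0.25 toward the next copy state (half the distance
between integer-copy ratios), which makes sub-threshold drift uncallable
while leaving true aneuploidies (deviation 0.5) untouched. Thresholds
default to z ≥ 3.5 for gains and z ≤ −3.5 for losses; all knobs are
arguments.

**Sex baseline.** Chromosomal sex is inferred from Y coverage (median Y
ratio ≥ 0.25 ⇒ XY); X and Y references follow (X: 1.0 female / 0.5 male).
A monosomy-X profile therefore presents as a female baseline with an X
loss. Sex-chromosome medians landing more than 0.15 away from every
integer-copy state are flagged "possible mosaic" rather than forced onto
an integer.

**Segmentation.** Ratios (divided by the chromosome baseline) are smoothed
with a centred 5-bin running median; bins < 0.75 or > 1.25 form
same-direction runs, runs separated by ≤ 1 bin are bridged, and runs
shorter than `min_size` (default 100 kb) are dropped. Copy number is
round(2 · baseline · mean ratio). The smoothing window and gap bridge
exist because duplications (ratio 1.5, proportionally noisier counts)
would otherwise fragment; both are parameters.

**Size tiers.** >5 Mb chromosomal; 100 kb–5 Mb submicroscopic (closed at
both ends — the boundary convention is not published, so the package fixes
one and regression-tests it at exactly 100 kb and 5 Mb); 50 bp–<100 kb
intragenic; <50 bp rejected.

### Stage 2: phenotype-driven SNV triage

Imaging phenotypes map to ontology terms; the candidate gene list is the
union of genes annotated to each query term *and all descendant terms*
(annotation propagation — standard ontology semantics; the alternative,
query-terms-only, would make the list sensitive to annotation granularity).
The shortlist filter retains variants with max(public MAF, in-house MAF)
≤ 0.01 — the maximum because "filtered if common in the public and
in-house databases" is ambiguous between AND/OR and the OR-style exclusion
is the stricter clinical reading — excluding intronic and noncoding
consequences. Canonical splice-site positions (±1–2 of an exon boundary)
are their own consequence class and survive the intron filter; deeper
intronic positions do not.

Classification is a deterministic combining-rule engine over curated
evidence tags (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7), applying the
published pathogenic/likely-pathogenic/benign combining criteria;
conflicting pathogenic- and benign-side evidence resolves to VUS, as does
an empty tag set. The engine deliberately does *not* generate evidence —
segregation, literature and functional judgments arrive as input, because
those are panel judgments no rule engine should fake. Missing in-silico
scores never count as damaging.

CNV classification uses evidence points on the published scale (≥ 0.99
pathogenic, 0.90–0.98 likely pathogenic; mirrored negative bounds on the
benign side). Points are curated where available; for synthetic data a
gene-count heuristic stands in (≥ 5 genes hit ⇒ 0.99; ≥ 1 ⇒ 0.95; none ⇒
0), which is a placeholder for dosage-sensitivity curation, not a claim
about real scoring.

P/LP findings without phenotype relevance are categorised secondary (gene
on the reporting panel), carrier (heterozygous in a recessive-disease
gene) or incidental, in that precedence. Phenotype relevance itself is an
explicit input (candidate-list membership by default) rather than an
inference, since the original relevance judgments were made by a clinical
panel.

### Stage 3: small CNVs

Events of 50 bp–100 kb are assessed only if they overlap ≥ 1 exon interval
and have in-house frequency < 0.01, ordered largest first, then classified
by the same evidence-point scale.

## Burden analysis

QC keeps variants with depth ≥ 20, alt-allele depth ≥ 3 and
max(len(ref), len(alt)) ≤ 5 bp (the span definition for "variant ≤ 5 bp"
is the package's choice; the source rule does not define it).
Loss-of-function = {nonsense, frameshift, canonical splice, stop-loss};
damaging missense requires SIFT damaging AND CADD > 20 AND M-CAP > 0.025
AND REVEL > 0.5, all strict. A singleton is an allele key
(chrom, pos, ref, alt) seen in exactly one sample of the counting
population — by default the combined case+control table, which keeps the
two arms' counts comparable; counting within cases only is a switch
(`singleton_population="cases"`). Per-sample counts are kept in nested
public-MAF strata {0, ≤ 0.001, ≤ 0.01} (MAF = 0 means absent from every
configured public source; the in-house database is excluded from the
strata because it defines the control arm and would be circular).

The two-sided Wilcoxon rank-sum test uses midranks; the exact null
distribution when min(n, m) ≤ 12 and the data are tie-free, otherwise a
normal approximation with tie-corrected variance and continuity
correction; p is clamped to (0, 1]. The distribution itself comes from
scipy's Mann–Whitney implementation; the exactness of the selection logic
is verified in the test suite against an independent exhaustive
enumeration of rank allocations.

## Synthetic cohorts

The generator's job is to produce data with the *statistical structure*
the pipeline assumes, at a scale where full runs take seconds.

* **Genome**: 24 chromosomes at 1/20 human proportions (chr1 ≈ 12.4 Mb),
  100 kb bins. Real-genome coordinates are accepted but not required.
* **Depth**: negative-binomial bin counts (overdispersion α = 0.005, i.e.
  ~9% coefficient of variation at the default 500 reads/bin — the scale of
  shallow-sequencing noise after mappability effects; α = 0 gives the
  Poisson limit), mean proportional to local copy number, multiplied by a
  quadratic GC droop (1 − 30·(gc − 0.42)²) over a deterministic smooth GC
  field shared by all samples.
* **Background variants**: per sample, Poisson(114) private variants with
  a consequence mix (10% LoF), depth ~ Poisson(42) with a 4% shallow
  fraction, indel spans occasionally exceeding 5 bp, and a population-MAF
  mixture (60% exactly 0, else Beta(0.5, 600)) so all MAF strata are
  populated; plus draws from a cohort-level panel of 300 shared
  polymorphic sites, which supply the non-singleton alleles. The private
  rate and the case excess (Poisson(4.2) cohort-unique QC-passing LoF
  variants per case) are calibrated so control and case singleton-LoF
  medians land near the published 9 and 13.5 at n = 136/200. With zero
  excess, cases and controls are exchangeable draws from one model.
* **Spikes**: aneuploidies (karyotype change), CNVs ≥ 100 kb (bin-level
  copy overrides), diagnostic SNVs (placed in a gene annotated to the
  target sample's phenotype terms, with evidence tags defaulting to
  {PVS1, PM2, PP4} ⇒ P), and intragenic CNVs (rows in the CNV table).
  Every spike is recorded in a truth table keyed by coordinates.
* **Randomness**: one global seed; each sample owns a generator stream
  derived from (seed, arm, index), so a sample's data survives cohort-size
  changes unchanged.

What the generator does **not** emulate: read-level errors and mappability
structure, linkage disequilibrium, relatedness, trio inheritance,
gene-length variation in mutability, and real dosage-sensitivity
annotation. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline logic* under the stated statistical model,
not the clinical performance of any detector on real sequencing data.

## Packaged fixture

The fixture re-encodes the published cohort tables: 162 case samples
(chromosomal sex 81/81; 114 CNS-only vs 48 CNS+other), 62 diagnosed
samples with their curated findings (18 aneuploidies; 21 CNV events
> 100 kb across 17 patients; 3 intragenic CNVs; 26 diagnostic SNVs across
24 patients), a gene→inheritance-mode table, and cohort metadata. Two
accountings coexist in the source: by *patient* (18+17+3+24 = 62) and by
*event* (21 CNVs, 26 SNVs); the fixture stores both and the yield
arithmetic uses patients. The "29 key genes" figure is an entry count
(26 SNV entries + 3 critical CNV genes); the distinct-gene count is 22,
and the 70/15/15 inheritance split is computed over the 20 distinct
small-variant genes — the only gene set that reproduces the printed
percentages exactly, and the natural one, since inheritance mode is a
property of single-gene disease. Resolution-tier denominators
(162→130→127→103) follow pure cascade shrinkage. One published CNV row
carries a cytoband label inconsistent with its coordinates (a chr2 locus
labelled 17q11.2); the fixture keeps the printed label but corrects the
chromosome. Attributes of undiagnosed samples beyond the published
marginals (their sex fill-in, phenotype labels, subgroup placement) are
synthetic and marked as such; per-phenotype yields are therefore encoded
only at the published anchors (hydrocephalus and NTD n = 34 each, 4 NTD
diagnoses). A checksum manifest guards the fixture files against silent
edits.

## Numerical conventions

Percentages round half away from zero (one decimal for yields, integer
for inheritance splits) — the convention that reproduces every printed
table percentage from its printed fraction. Small-variant coordinates are
1-based; interval maps are 0-based half-open; CNV calls are 1-based
inclusive with size = end − start + 1; all conversions happen in
`io_formats`. Frequencies absent from a database are 0. Ties in the
small-CNV ordering break by insertion order after the size sort
(stable sort).

## Problem sizes in the test and acceptance runs

The suite exercises: 50 simulated profiles per aneuploidy/CNV power
estimate; 500 null cohorts (136/200 samples each) for rejection-rate
calibration and 100 spiked cohorts for power; 10⁴-record random tables
for each predicate oracle; exhaustive rank-enumeration up to
min(n, m) = 7. The acceptance script uses the same profile counts and a
100-cohort null calibration.
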