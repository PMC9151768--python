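# Methods

This note documents the models, rules and numerical choices behind
`editscape`, and what the synthetic-data generator does and does not
emulate.

## Coordinates, strand and data model

All coordinates are 1-based with closed intervals (the pileup/VCF
convention); BED output converts to 0-based half-open at the boundary.
Editing sites are always described on the annotated transcript strand: a
site in a minus-strand gene is an A on the transcript but appears as T>C on
the reference, and the counting layer complements accordingly (G counts for
'+' sites, C counts for '−' sites). Pileup tables carry reference-strand
base counts and always satisfy coverage = A + C + G + T.

The central container is `SiteMatrix`: aligned site × sample matrices of
editing level (edited/coverage, missing where a sample fails the calling
thresholds), coverage and edited counts, plus sample metadata. Coverage and
edited counts are kept even where the level is missing, because the
re-query step needs them.

## Site calling and the filter cascade

De novo calling emits every position whose dominant alternate base reaches
coverage ≥ 10, alternate reads ≥ 3 and ratio ≥ 5%; all twelve substitution
types are kept (C>T and G>A are tagged provisional downstream). A position
is multi-allelic when two or more alternate bases each reach 3 reads and 1%
of coverage — robust to singleton miscalls.

The cascade applies six rules in a fixed order, counting removals per rule
so that input = retained + Σ removed always holds: (1) multi-allelic in any
sample; (2) no sample passes the coverage/edited/ratio thresholds; (3)
blacklist or homopolymer overlap; (4) known SNP with MAF > 0.05; (5) within
5 bp of a splice site; (6) no cell type detects the site in ≥ k of n
samples (default 8 of 9). Thresholds are inclusive (≥ 10, ≥ 3, ≥ 5%), and
the 5% ratio is evaluated per sample: a sample "detects" a site only if its
own ratio passes. Both choices are exposed as parameters.

The re-query step takes sites detected in exactly one cell type and labels
the other cell types `covered-unedited` (median coverage ≥ 10 with median
edited reads < 3 across that cell type's samples — coverage without
editing) or `insufficient-coverage` (anything else). Medians across
samples are used rather than pooled counts so that a single deep library
cannot dominate the call. Median imputation operates within one cell type
at a time and refuses to impute a site with no observed value in the group.

Annotation assigns exactly one genic region per site with precedence
CDS > 5′UTR > 3′UTR > splice-adjacent > intron > downstream-TSS >
intergenic; splice-adjacent sits between the exonic classes and intron
because such sites are flagged for removal, and `downstream-TSS` means
within 1 kb of a TSS but outside any gene body. Repeat class (Alu > L1 >
none) and catalog membership (exact chrom/pos/strand match) are independent
axes. The recoding flag translates the reference and edited codons with the
standard genetic code on the spliced CDS of the covering gene.

## Global metrics

**AEI.** The Alu editing index is Σ(edited reads at Alu adenosines) /
Σ(coverage at Alu adenosines), strand-aware per Alu element. It is
invariant to row order and to uniform coverage scaling at a fixed edit
fraction, and undefined (an error) when no Alu adenosine is covered.

**Hyper-editing.** Reads dense in A>G edits fail normal alignment, so the
detector collapses the edited base pair: A→G in reads and genome for the
sense pass, T→C for the antisense pass, trying both read orientations.
Alignment is exact k-mer seeding (k = 16, seeds at both ends and the
middle) with ungapped comparison; a read must align to exactly one locus
with ≤ 3 transformed mismatches or it is discarded as ambiguous and
reported. This replaces the bwa-based alignment of the published
hyper-editing tool; at the ≤ 10 Mb scale this package targets, the unique
transformed-alignment contract is the same. After restoring the original
sequences, a read is hyper-edited if it carries ≥ 5 A>G sites covering
≥ 60% of the adenosines in its window while total mismatches stay ≤ 90% of
its length (the published per-read thresholds; all exposed as parameters).
Sites at SNPs with MAF > 0.05 are dropped. Sites within 100 bp are grouped,
cluster bounds are extended by the mean inter-site distance on both ends,
and overlapping clusters are merged; merging is idempotent. The normalized
signal is sites per million mapped bases, exactly n/MM × 10⁶, with
mapped-base counts taken from sample metadata.

**Motifs.** Nucleotide frequencies at ± 4 bp around the edited adenosine
(read on the site strand, so the centre is 100% A) are compared against
genome-wide adenosine contexts on both strands (subsampled to 50 000) as
log₂ ratios with a pseudocount of 1 per cell, capped at ± 8 so empty cells
stay finite.

## Differential editing and specificity

Per site, editing ~ cell type + age + PMI is fitted by generalized least
squares with a compound-symmetry covariance within donor. The consensus
intra-donor correlation ρ̂ is estimated once across all sites from
first-pass OLS residual cross-products, de-biased by the hat matrix
(OLS residuals satisfy E[eᵢeⱼ] = −σ²Hᵢⱼ under independence; without the
correction ρ̂ is pulled negative and null p-values drift from uniform).
This is the analogue of limma's duplicateCorrelation; a donor fixed-effect
fallback exists but absorbs donor-level covariates such as age and PMI,
which is why GLS is the default. Sites with no within-group variation get
p = 1 and a degenerate flag rather than an exception. p-values are BH
adjusted across all sites of a contrast; Δ editing is the difference of
group means on the 0–1 scale; Cohen's d pools SDs by degrees of freedom.
A secondary model adds ADAR1/ADAR2 expression as covariates.

Specificity labels partition sites: `specific:<ct>` requires detection in
exactly one cell type plus re-query evidence for the other two;
`enriched:<ct>` requires detection in ≥ 2 cell types and at least one
contrast won at FDR < 0.05 (the winner of the most significant contrast
names the label; all significant contrasts are recorded as evidence);
everything else is `shared`.

**Variance partitioning** attributes per-site variance sequentially: the
designed grouping factor (cell type) first via the unbiased between-group
moment estimator (between-group variance of group means minus the
within-group noise share, clipped at zero), then continuous covariates in
a joint linear fit (each contributing Var(x_f β_f)), then donor as a second
grouping factor, then the residual; fractions are normalized to sum to 1.
A joint fixed-effect fit is impossible here — donor indicators are exactly
collinear with donor-level covariates — and the sequential scheme keeps the
designed cell-type contrast from being soaked up by incidental sample-level
covariates. Fractions are invariant to affine rescaling of continuous
covariates; exactly collinear continuous factors raise an error naming the
pair. The eight default factors are cell type, donor, age, pH, PMI and
ADAR1/2/3 expression.

**Set and region overlap.** Gene/site set overlap uses a one-sided
(greater) Fisher exact test on the 2×2 table against an explicit
background, with the sample odds ratio capped at 10⁶ when a margin is
empty. Regional overlap significance comes from permutation: each of the
(default 1000) permutations redraws the query regions uniformly within
their own chromosome, preserving lengths and per-chromosome counts;
p = (1 + #{perm ≥ observed}) / (n_perm + 1). The default overlap statistic
is total overlapping bases rather than the count of overlapping regions:
the count statistic is heavily tied under permutation, which makes the
empirical p conservative and visibly non-uniform under the null, while the
base-overlap statistic keeps the null p close to uniform. The count
statistic remains available as an option.

## Pseudo-bulk validation

Nuclei are assigned to pools by marker presence with a fixed precedence:
RBFOX3⁺SOX6⁺ → MGE-GABA, RBFOX3⁺SOX6⁻ → GLU, then (all RBFOX3⁻) SOX10⁺ →
OLIG, GFAP⁺ → astrocyte, CLDN5⁺ → endothelial, TMEM119⁺ → microglia, else
unassigned; presence means a nonzero count (threshold configurable).
Sorted-population sites are re-quantified per pool replicate at coverage
≥ 10 (a 3–20 sweep mode exists; site counts are monotone in the
threshold). A site validates when the pool median across replicates lies
within 50% of the sorted-population median, read relatively:
|pool − FANS| ≤ 0.5 · FANS. An absolute reading (± 0.5 in level units)
would validate almost everything and is offered only as a config switch.
A FANS median of exactly 0 validates only a pool median of 0 and is
flagged, since the relative rule is degenerate there. The TSS-bias test
bins sites into high (top quintile), medium (middle three) and low (bottom
quintile) coverage and compares TSS distances of validated vs non-validated
sites by a two-sided Mann–Whitney U test, overall and per bin, skipping
comparisons with fewer than two sites on a side.

## Deconvolution and saturation

Counts are filtered to genes with CPM ≥ 1 in ≥ 50% of samples (inclusive)
and log₂(CPM + 1) transformed. Fractions solve min‖S f − b‖ s.t. f ≥ 0 per
sample over the shared genes (scipy's active-set NNLS; unique when
signature columns are independent); excitatory and inhibitory estimates are
summed into one neuronal fraction before normalizing to sum to 1.
Detection saturation retains sites detected in ≥ t·n samples over a
threshold grid and tracks the cell-type-associated share
(specific ∪ enriched labels). Fold enrichment between the ≥ 90% and ≥ 10%
thresholds is a share ratio by default (a count-ratio definition is a
switch), with significance by label permutation.

## cis-edQTL mapping

Sites observed in < 50% of donors are dropped; remaining missing values are
imputed by predictive mean matching: each incomplete site is regressed on
its ≤ 10 most-correlated complete sites, and every missing donor copies the
observed value of one of its k = 5 nearest neighbours in predicted value
(seeded choice); per-site median imputation is the fallback. For every
SNP–site pair within 1 Mb, editing ~ dosage + sex + age + RIN + death type
is fitted; death type enters as unordered dummy contrasts. The fit uses
Frisch–Waugh residualization against the covariates, which is algebraically
identical to the full normal-equation OLS (and verified against it to
1e-10 in the tests). BH FDR is computed across all pairs of all
chromosomes jointly; monomorphic SNPs are skipped with a report. The
max-edQTL per site is the minimum-p significant pair, with ties broken by
larger |β|, then smaller |distance|, then SNP id.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
realistic reads. Genomes are random sequence with planted gene models
(three exons, UTRs, CDS, splice sites at exon boundaries), A-rich Alu
elements (~45% A on the annotated strand, so AEI denominators are never
empty), L1 elements, blacklist windows, homopolymer runs (≥ 6 bp) and SNPs
with MAFs spanning the 0.05 boundary. Editing truth plants sites on genic
adenosines in six classes (three cell-type-specific classes, enriched with
a configurable difference δ = 0.2, shared-equal, and never-edited null
sites); by default sites avoid positions a faithful cascade always removes
(splice-adjacent, homopolymer, blacklist, common SNPs), since those are
unrecoverable by construction. True rates default to Beta(2,3) rescaled to
[0.10, 0.95]: the pipeline's own 5% ratio threshold makes substantially
lower-level sites undetectable by definition, so the floor reflects the
population of callable sites; the raw Beta(2,3) (or any other shape) is a
parameter away. Pileups draw coverage ~ Poisson (default mean 100 for the
deep sorted-population design) and edited reads ~ Binomial(coverage, rate),
with uniform miscalls at ε = 0.001 on unedited reads — the simplest error
model that exercises the ratio filter. The default design is 3 cell types
× 9 donors with age/PMI/pH/sex/RIN covariates and cell-type-structured
ADAR1/2/3 expression.

Hyper-edited reads convert exactly ⌈density × #A⌉ adenosines per read
(default 60%) at randomly chosen positions, so every planted read carries
at least the configured fraction — an i.i.d. per-base coin would leave
~half the reads below their own nominal density and make recovery of a
planted cluster a coin flip at the detector's matching 60% threshold.
Genotypes follow Hardy–Weinberg at MAF ∈ [0.05, 0.5]; causal SNPs sit
within 50 kb of their site and shift the donor's true rate by β per
alternate allele, clipped to [0, 1] (fully clipped effects are recorded as
warnings). Pseudo-bulk pools scale coverage with pool size and decay it
exponentially with the relative distance from the transcript 3′ end; bulk
mixtures are signature · fractions + Gaussian noise floored at 0.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mapping and alignment artefacts, base-quality
structure, PCR duplicates, overlapping mates, splicing-aware coverage,
realistic repeat sequence (Alu elements are compositionally, not
phylogenetically, Alu-like), linkage disequilibrium between SNPs, and any
empirical distribution of editing levels. Recovery results certify the
statistical machinery, not robustness to upstream artefacts.

## Problem sizes and defaults used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated data
at desk scale, chosen so the whole suite completes in well under the time a
coffee takes: 2 × 100 kb genomes, 200–300 planted sites, 9 donors × 3 cell
types, 12 hyper-editing clusters of 4 reads, 150 genotyped donors with 20
causal SNPs, 1000-site differential designs, 5000 independent null
SNP–site pairs, 1000-fold permutation tests. All thresholds are the
pipeline defaults stated above; none are tuned per run.

## Known limitations

- The k-mer aligner is exact-match seeded and ungapped; it is not suitable
  for genomes with long exact repeats (seeds become ambiguous and reads are
  discarded) or for indel-containing reads.
- The compound-symmetry GLS treats ρ̂ as known; with very few sites the
  shared estimate is noisy and p-values are only approximately exact.
- Variance fractions are sequential-attribution estimates, not REML
  variance components; shared variance between cell type and covariates is
  credited to cell type by design.
- PMM imputation assumes the missing mechanism is ignorable given the
  correlated complete sites.
- `overlap_enrichment` treats elements as exchangeable; it does not match
  on gene length or expression.
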