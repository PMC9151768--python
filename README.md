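# editscape

Cell-type-resolved analysis of A-to-I RNA editing in the brain, as a tested,
reusable Python pipeline. Adenosine-to-inosine editing — catalysed by the
ADAR enzymes, read as A>G mismatches in RNA-seq — differs sharply between
neuronal and glial populations, and most published editing catalogs are
blind to that cellular structure. `editscape` implements the full analysis
a study of sorted brain cell populations needs:

- **Site discovery and filtering** — de novo A>G mismatch calling plus
  supervised quantification of a known-sites catalog, followed by an ordered
  six-rule cascade (multi-allelic removal; coverage ≥ 10, edited reads ≥ 3,
  editing ratio ≥ 5%; blacklist/homopolymer exclusion; common-SNP removal at
  MAF > 0.05; splice-site proximity ± 5 bp; detection in ≥ 8 of 9 samples
  per cell type), with an auditable per-rule removal report.
- **Global editing indices** — the Alu editing index
  (AEI = Σ edited reads / Σ adenosine coverage within Alu elements, strand
  aware) and hyper-editing detection by base-collapsed realignment (A→G /
  T→C transformation, unique k-mer-seeded alignment, per-read thresholds,
  cluster extension by the mean inter-site distance and overlap merging),
  normalized as sites per million mapped bases (n/MM × 10⁶).
- **Cell-type statistics** — covariate-adjusted differential editing
  (editing ~ cell type + age + PMI, donor as a repeated measure via a
  consensus intra-donor correlation and compound-symmetry GLS), BH FDR,
  Cohen's *d*, specific/enriched/shared classification backed by a
  third-round re-query of the other cell types, variance partitioning,
  gene-level editing density (sites / log₂(length + 1)) with 99%-interval
  outliers, Fisher-exact set overlap, and a regioneR-style permutation test
  for regional overlap.
- **Pseudo-bulk validation** — marker-based pool assignment (RBFOX3 / SOX6 /
  SOX10 / GFAP / CLDN5 / TMEM119), re-quantification at coverage ≥ 10, the
  50%-of-median concordance rule, and a Mann–Whitney test for 3′/TSS
  positional bias of validated sites.
- **Bulk deconvolution** — NNLS cell-type fractions on log₂-CPM expression
  against a signature matrix with neuronal summation, detection-saturation
  curves and 90%-vs-10% fold-enrichment.
- **cis-edQTL mapping** — editing ~ dosage + sex + age + RIN + death type
  within 1 Mb windows, BH FDR across all pairs jointly, max-edQTL selection,
  SNP–site distance profiles and cell-type annotation of hits.
- **A synthetic-data generator** — genomes with gene models, A-rich Alu
  elements, blacklist/homopolymer/SNP annotations; binomial per-site editing
  with cell-type-structured true rates; hyper-edited reads; Hardy–Weinberg
  genotypes with additive cis effects; pseudo-bulk pools with 3′ coverage
  bias; and bulk mixtures — so every stage is testable against known ground
  truth without access-restricted data.

## Worked example

```python
import editscape as es
from editscape.pipeline import discover_and_classify

genome = es.build_synthetic_genome(seed=1)
truth = es.simulate_editing_truth(genome, n_sites=300, seed=2)
samples = es.simulate_pileups(truth, genome, mean_coverage=50, seed=3)

labels, matrix, report = discover_and_classify(samples, genome)
print(report.to_frame())
print(labels["label"].value_counts())
```

prints the cascade audit and the classification of the retained sites:

```
                    rule  removed
0          multi-allelic        0
1             thresholds        0
2  blacklist-homopolymer        0
3             common-snp        0
4        splice-adjacent        0
5         detection-rate        1
6               retained      254
label
shared               55
specific:MGE-GABA    45
specific:GLU         45
specific:OLIG        44
enriched:GLU         25
enriched:OLIG        21
enriched:MGE-GABA    19
Name: count, dtype: int64
```

Every retained site is genuine — the 45 never-edited positions planted by
the generator are all rejected, along with the 200 error-only background
adenosines — and the specific/enriched/shared labels match the generator's
truth for ~98% of sites at mean coverage 50.

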