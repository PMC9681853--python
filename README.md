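# pancscreen

Pan-cancer screening of a focal gene or gene family from bulk expression
cohorts. The package asks, for one gene of interest (e.g. an enzyme suspected
of being silenced in tumors): is it consistently downregulated across cancer
types, anticorrelated with tumor aneuploidy, depleted of somatic mutations,
and embedded in a tumor-rewired co-expression program? It is a library for
computational biologists analyzing TCGA-style cohorts (genes × samples
expression, sample annotations, mutation and methylation tables, GMT gene
sets), plus a synthetic cohort generator that plants every effect the screen
assumes so each statistical stage has a parameter-recovery oracle.

## The statistics at the core

* **Per-cancer differential expression.** For each cancer type with ≥ 20
  samples in both arms, a two-sided Wilcoxon rank-sum test of log₂(x+1)
  expression, tumor vs unmatched healthy solid tissue, plus a pooled PANCAN
  row; direction called from the sign of the median difference at p < α.
* **Family consistency.** If the focal gene is called *down* in k of n
  cancers, P(K ≥ k | n, p₀ = 1/3) — the binomial tail under a trinary null
  (down/up/ns equally likely). For k = n = 13 this is (1/3)¹³ ≈ 6.3 × 10⁻⁷.
* **Genome-wide empirical null (one-sample Z).** The focal gene's Spearman
  correlation with per-sample aneuploidy scores (per cancer, median across
  cancers for PANCAN) — or its mutation rate per kilobase — is standardized
  against the same statistic over all genes: z = (v − mean)/sd, one-sided
  p = Φ(z) for the lower tail.
* **Differential co-expression (ΔNES).** Spearman co-expression signatures
  of the focal gene in tumor and healthy samples are scored against a
  gene-set collection with a from-scratch preranked GSEA (running-sum ES,
  weight exponent 1, gene-permutation NES and p, BH FDR); ΔNES =
  NES_tumor − NES_healthy ranks tumor-rewired regulator programs.
* **Downstream checks.** Regulator-based tumor stratification (top/bottom
  decile), control-normalized oncogene-overexpression effect tests, promoter
  methylation comparison, and the background-subtracted immunofluorescence
  intensity ratio (PTM channel over tubulin).

## Worked example

```python
import pancscreen as ps
from pancscreen.empirical_null import genomewide_association, pancan_median_association

cfg = ps.CohortConfig(rng_seed=1)        # 13 cancers, 25+25 samples, 2000 genes
cohort = ps.generate_cohort(cfg)         # focal gene planted down 1.5 log2 units

results = ps.diffexp_per_cancer(cohort.expression, cohort.samples, cfg.focal_gene)
directions = [r.direction for r in results if r.cancer_type != "PANCAN"]
p, k, n = ps.family_consistency_binomial(directions)
print(f"down in {k}/{n} cancers, binomial p = {p:.2e}")

tables = {ct: genomewide_association(cohort.expression, cohort.samples, ct)
          for ct in cfg.cancer_types}
medians, aneu = pancan_median_association(tables, cfg.focal_gene, tail="lower")
print(f"median rho = {medians[cfg.focal_gene]:.3f}, lower-tail p = {aneu.p_one_sided:.4f}")
```

prints

```
down in 13/13 cancers, binomial p = 6.27e-07
median rho = -0.393, lower-tail p = 0.0000
```

meaning: the planted downshift is recovered as a *down* call in every cancer
type, the consistency of those 13 calls is wildly unlikely under the trinary
null (6.3 × 10⁻⁷), and the focal gene's median expression–aneuploidy
correlation (−0.39 at this seed; the planted target is −0.3) sits far in the
lower tail of the genome-wide distribution.

The `examples/` directory has one short script per capability (cohort
screen, aneuploidy association, mutation depletion, co-expression rewiring,
oncogene overexpression, immunofluorescence quantification); each builds a
small input, runs the method and explains the numbers it prints.

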