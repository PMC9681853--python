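# Methods

`pancscreen` implements a pan-cancer screen asking whether one focal gene is
consistently dysregulated in tumors across many cancer types, and whether its
regulatory context is rewired. This note describes the statistical model of
each stage, the synthetic cohorts used to validate them, the numerical
choices, and the known limitations.

## The screen

### Per-cancer differential expression and the consistency test

For each cancer type with at least `min_samples_per_arm` (default 20) samples
in both the healthy-solid and primary-tumor arms, the focal gene's
log-normalized expression (log2(x+1)) is compared between arms with a
two-sided Wilcoxon rank-sum test. A direction call per cancer is *down* or
*up* from the sign of median(tumor) − median(healthy) when p < α (default
0.05), otherwise *ns*. A PANCAN row pools all retained cancers. P-values are
reported nominally; a BH adjustment across cancers is available but off by
default, matching the usual presentation of per-cancer panels.

Family-wide consistency: for a gene called *down* in k of n cancers, the
binomial tail P(K ≥ k | n, p₀) with p₀ = 1/3 (the three calls equally likely
under no consistent effect) measures how surprising that consistency is.
With k = n = 13 this reduces to (1/3)¹³ ≈ 6.3 × 10⁻⁷. Both n and p₀ are
parameters, not constants; p₀ = 1/3 is a deliberate, simple trinary null and
other nulls (e.g. estimated per-gene call frequencies) could be substituted.

### Genome-wide empirical nulls (one-sample Z tests)

Two focal-gene statistics are judged against the distribution of the same
statistic over all genes rather than against a parametric sampling
distribution:

* **Aneuploidy association** — per cancer, the Spearman correlation ρ between
  each gene's expression and the per-sample aneuploidy score over scored
  tumor samples; pan-cancer, the per-gene median ρ across cancers (genes with
  a finite ρ in every cancer).
* **Mutation depletion** — per cancer (and optionally per mutation effect
  class), each gene's mutation count divided by its length in kb; pan-cancer,
  the per-gene median rate.

The focal gene's value v is standardized against all genes' values,
z = (v − mean)/sd with sample sd (n−1), and the one-sided p is Φ(z) (lower
tail, the default for both anticorrelation and depletion) or 1 − Φ(z). The
rank-based empirical quantile of v is reported alongside as a diagnostic.
The Z test is exact only insofar as the genome-wide distribution is normal —
see Limitations.

### Differential co-expression (delta NES)

The focal gene's co-expression signature in one sample class is the vector
of Spearman correlations between the focal gene and every other gene across
all samples of that class, pooled over cancer types (pooling keeps one
well-powered signature; per-cancer signatures with median aggregation would
be a straightforward variant). Each signature is run through preranked GSEA
against a transcription-factor target-set collection; ΔNES = NES(tumor) −
NES(healthy) per set measures tumor-specific rewiring. A set *qualifies*
when its BH FDR is below `fdr_threshold` (default 0.05) in at least one
class; NES is computed in both classes regardless, since dropping
non-enriched sets loses information and the filter is recorded as a flag.
Tumor and healthy runs share per-set permutation seeds, so comparing a
signature against itself gives ΔNES exactly zero for every set.

### Preranked GSEA engine

Classic weighted Kolmogorov–Smirnov running sum with weight exponent 1
(configurable): walking down the ranked list, a member advances the sum by
|score|/Σ|member scores| and a non-member retreats it by 1/(N − n_set); the
enrichment score (ES) is the signed maximal deviation from zero. When the
largest positive and negative deviations tie in magnitude to within 1e-9,
the positive one is returned (ties occur only on contrived rational inputs).
The null is **gene permutation** — ES of random same-size sets from the same
signature — matching preranked GSEA semantics. NES divides ES by the mean
|null ES| of matching sign; p = (1 + #{same-sign nulls at least as extreme})
/ (1 + #{same-sign nulls}), so min p = 1/(m+1). BH FDR is applied across all
tested sets. Set-size bounds default to 5–5000 members present in the
signature. Permutations are vectorized over member positions (the running
sum is piecewise linear, so extrema occur only adjacent to hits), making
1000 permutations × 20 sets ≈ 1 s on one core at 2000 genes.

### Regulator stratification

Within each cancer type's tumor arm, samples in the top decile (nearest-rank
k = ⌈f·n⌉, boundary ties included) of **either** regulator form
`regulator_high`; samples in the bottom decile of **all** regulators form
`regulator_low`. Strata are computed per cancer, and PANCAN pools per-cancer
labels. A cancer where the two strata would overlap (e.g. a fully tied arm),
or with fewer than 1/f tumor samples, is skipped with a warning. Each
stratum is compared against the unmatched healthy arm with the same Wilcoxon
machinery.

### Oncogene-overexpression effect test

The in-vitro check uses a 4 cell-line × {empty vector, 3 oncogenes} × 2
timepoints × 2 replicates design (64 samples, 16 induced per oncogene). Each
sample's log2(TPM+1) for the target gene is normalized by subtracting the
mean of the matched empty-vector arm (same cell line and timepoint), which
cancels cell-line and timepoint baselines exactly; each oncogene's induced
samples are then compared to the empty-vector samples by Wilcoxon rank-sum.

### Promoter methylation

The promoter window is the `promoter_window_bp` (default 1500) bases
upstream of the TSS, strand-aware and half-open in 0-based coordinates
([TSS−w, TSS) on +, (TSS, TSS+w] on −). The per-sample statistic is the
median beta of chromosome-matched probes in the window; tumor vs healthy is
tested per cancer by Wilcoxon. A gene with no in-window probes is reported
untestable rather than silently skipped.

### Immunofluorescence normalized intensity

For an ROI measured identically in a PTM channel x and the tubulin channel:

    NI = (RawIntensity_x − Area·mean Noise_x) / (RawIntensity_tub − Area·mean Noise_tub)

Raw intensities are ROI sums (noise means are per-unit-area, hence the Area
product), noise means average ≥ 3 background regions (fewer warns), and a
non-positive denominator is an error naming the ROI. The ratio is invariant
to common channel gain and to constant per-area background added
consistently to a channel and its noise estimate; both invariances are
verified to machine precision in the test suite.

## Synthetic cohorts

`generate_cohort` plants every effect the screen assumes and records the
realized effect sizes in a `CohortTruth`, so downstream tests are
parameter-recovery tests. Defaults (the study conditions all calibration and
recovery suites use): 13 cancer types, 25 healthy + 25 tumor samples each,
2000 genes.

* **Expression** — per-gene baseline mean ~ U(1, 10), per-sample noise
  N(0, 1), in log2 units, clipped at 0 to respect non-negativity (clipping
  touches only low-baseline genes). The focal gene is shifted by
  `focal_downshift` (default −1.5) in every tumor arm.
* **Aneuploidy** — per cancer, tumor scores are a rounded, clamped affine map
  of a latent variable correlated with the focal gene's standardized
  expression. The latent Pearson correlation is calibrated to the target
  Spearman ρ_s (default −0.3) by the exact bivariate-Gaussian identity
  r = 2·sin(π·ρ_s/6); this closed form solves the calibration problem a
  numeric root-finder on the noise scale would otherwise solve. Realized
  per-cancer Spearman correlations are recorded; over 20 seeds their mean
  sits within ±0.05 of the target.
* **Co-expression rewiring** — one designated TF target set shares a
  per-tumor-sample latent factor with the focal gene (weight 0.6 by default,
  zero loading in healthy samples), giving members a tumor-only co-expression
  of roughly w²/(1+w²) ≈ 0.26 with the focal gene.
* **Mutations** — per gene and cancer, counts ~ Poisson(base_rate ×
  length_kb × per-cancer sample count), with gene lengths log-uniform on
  [500 bp, 100 kb] (a realistic span that makes the per-kb normalization
  matter) and the focal gene's rate multiplied by `focal_depletion_factor`
  (default 0.2). Every count is materialized as a mutation record assigned
  to a random tumor sample with an effect class, so record-level and
  aggregated counts conserve exactly.
* **Methylation** — `n_probes_per_gene` probes within ±2 kb of each TSS with
  Beta(2, 5) betas, identical in both arms by default (the screen's
  methylation stage is a negative control here).
* **Overexpression experiment** — log2 TPM baselines U(1, 8) with per
  (gene, cell line, timepoint) context shifts (sd 0.3) and replicate noise
  (sd 0.3); CCNE1 and CDC25A multiply the focal gene's TPM by 0.7, MYC by
  1.0.

One global seed drives everything; each stage (and each gene set's
permutation null) derives its own generator by SHA-256 hashing of
(seed, stage name), so stages are reproducible in isolation and replicated
suites draw their per-replicate seeds the same way.

**What the generator does not emulate:** batch effects, tumor purity,
copy-number-driven expression dosage, gene–gene correlation beyond the one
planted factor, mutation hotspots or trinucleotide context, and realistic
methylation covariance. Passing recovery tests therefore demonstrates that
the statistics detect the planted structure at realistic sizes and stay
calibrated under exchangeable nulls — not that they are robust to those
real-data complications.

## Problem sizes in the test suite

Recovery suites use 20 replicate cohorts at the default size; null
calibration uses 200 replicates for p-uniformity and 100 for the ΔNES
qualifying count; GSEA null uniformity uses 500 random sets at 500
permutations; the Wilcoxon size check uses 1000 null replicates at n = 20
per arm. These sizes put the whole suite at a few minutes on one core while
keeping the binomial checks well inside their stated bands.

## Numerical choices

* Wilcoxon: exact enumeration when n+m ≤ 16 without ties, otherwise the
  normal approximation with tie and continuity corrections; two samples with
  all values identical return p = 1 with a warning.
* Spearman: Pearson on average ranks (tie-aware); constant vectors give NaN
  with a warning; missing values are dropped pairwise.
* Standardization uses the sample sd (n−1).
* BH: step-up with enforced monotonicity, capped at 1 (statsmodels).
* Signature ranking: stable sort, ties broken by lexicographic gene id, so
  signatures are invariant to input order.
* All internal genomic coordinates are 0-based; BED output is half-open.
* TSV floats are written in shortest-repr form and parsed in round-trip
  mode, so write→read→write is byte-stable.

## Known limitations

* **Normality of the empirical null.** The one-sample Z test converts the
  focal gene's genome-wide standing into a p-value through Φ(z), which is
  calibrated only when the per-gene statistic is approximately normal across
  genes. The median Spearman ρ satisfies this well (null p-values uniform:
  KS p ≈ 0.9 over 200 replicate cohorts). The median mutation rate per kb
  does **not** at desk-scale cohort sizes: counts are small and lengths span
  two orders of magnitude, so the per-gene medians are left-skewed with an
  atom of zeros from short genes (skew ≈ −1, excess kurtosis ≈ 3), and the
  null p-values deviate from uniformity (KS D ≈ 0.16–0.20 over 200
  replicates) even though the planted depletion is detected reliably and the
  accompanying empirical quantile is uniform by exchangeability. The
  calibration test in `tests/test_acceptance.py` asserts uniformity for all
  three focal tests and the mutation case fails by design — it documents the
  Z approximation's breakdown rather than hiding it. Users screening
  mutation rates at small sample counts should read the empirical quantile,
  not the normal-theory p.
* Direction calls use nominal per-cancer p-values; the binomial consistency
  test treats calls as independent across cancers.
* The stratification decile rule is inclusive nearest-rank; heavily tied
  expression can enlarge strata or (fully tied) skip a cancer.
* `aneuploidy_coupling` targets the latent construction; rounding to integer
  scores and score clamping attenuate the realized correlation by a few
  hundredths at the default range.
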