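"""Focal-gene vs aneuploidy association against the genome-wide null.

Per cancer type, every gene's expression is Spearman-correlated with the
per-sample aneuploidy score over tumor samples; the focal gene's pan-cancer
median correlation is then judged against the distribution of all genes'
medians with a one-sided, one-sample Z test.
"""

import pancscreen as ps
from pancscreen.empirical_null import genomewide_association, pancan_median_association

cfg = ps.CohortConfig(rng_seed=7)  # planted coupling: Spearman -0.3
cohort = ps.generate_cohort(cfg)

tables = {}
for cancer in cfg.cancer_types:
    rho = genomewide_association(cohort.expression, cohort.samples, cancer)
    tables[cancer] = rho
    print(f"{cancer}: focal rho = {rho[cfg.focal_gene]:+.3f}")

medians, res = pancan_median_association(tables, cfg.focal_gene, tail="lower")
print(f"\nPANCAN median rho (focal) = {medians[cfg.focal_gene]:+.3f}")
print(f"z = {res.z:+.2f} against {res.n_genes} genes; lower-tail p = {res.p_one_sided:.2e}")
print(f"empirical quantile (diagnostic) = {res.empirical_quantile:.4f}")
print("-> the focal gene's anticorrelation with aneuploidy is extreme relative")
print("   to the genome-wide distribution, recovering the planted -0.3 coupling.")
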