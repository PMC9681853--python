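"""Tumor-rewired co-expression via delta NES.

Builds the focal gene's Spearman co-expression signatures in tumor and
healthy samples, scores a transcription-factor target-set collection on both
with preranked GSEA (paired permutation seeds), and ranks sets by
Delta NES = NES(tumor) - NES(healthy). The synthetic cohort plants one set
whose members share a tumor-only latent factor with the focal gene.
"""

import pancscreen as ps
from pancscreen.coexpression import (
    coexpression_signature,
    delta_nes_analysis,
    rank_targets_by_coexpression,
)

cfg = ps.CohortConfig(rng_seed=7)
cohort = ps.generate_cohort(cfg)

sig_tumor = coexpression_signature(cohort.expression, cohort.samples, cfg.focal_gene, ps.TUMOR)
sig_healthy = coexpression_signature(cohort.expression, cohort.samples, cfg.focal_gene, ps.HEALTHY)

records = delta_nes_analysis(
    sig_tumor, sig_healthy, cohort.gene_sets, n_permutations=1000, seed=cfg.rng_seed
)
print(f"{'set':<6}{'NES_t':>8}{'NES_h':>8}{'dNES':>8}  qualifies")
for r in records[:5]:
    print(f"{r.set_name:<6}{r.nes_tumor:>8.2f}{r.nes_healthy:>8.2f}"
          f"{r.delta_nes:>8.2f}  {r.qualifies}")
print(f"(planted rewired set: {cfg.rewired_set})")

top = rank_targets_by_coexpression(sig_tumor, cohort.truth.rewired_members, top_k=5)
print("\nstrongest tumor co-expression among rewired-set members:")
for gene, rho in top.items():
    print(f"  {gene}: rho = {rho:+.3f}")
print("-> the planted set tops the qualifying Delta-NES ranking: its members")
print("   co-express with the focal gene in tumors but not in healthy tissue.")
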