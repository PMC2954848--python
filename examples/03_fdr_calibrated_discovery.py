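"""Differential discovery with balanced-permutation FDR calibration.

Detects brain-vs-liver spike genes with per-gene t-tests; the critical
p-value is tuned so the permutation-estimated FDR stays below 10%. The
permutation null keeps equal numbers of brain and liver samples in each
pseudo-group, so the tissue signal vanishes while the globin artifact
still inflates the null — exactly what penalizes unmitigated protocols.
"""

from globinbench import (balanced_permutations, calibrate_threshold,
                         default_design, default_profiles,
                         generate_expression, ttest_per_gene)
from globinbench.benchmark import realized_fdr

profiles = default_profiles()
for name in ("no_treatment", "pna", "cdna"):
    design = default_design(1, protocols=(name,))
    expr, truth = generate_expression(design, profiles[name],
                                      n_genes=20_000, seed=2)
    stats = ttest_per_gene(expr, design.tissues)
    scheme = balanced_permutations(design.tissues, seed=2)
    cal = calibrate_threshold(stats["p_value"].to_numpy(), scheme, expr,
                              target_fdr=0.1)
    declared = set(stats.loc[stats["p_value"] <= cal.critical_p, "gene_id"])
    fdr = realized_fdr(declared, truth.de_genes)
    print(f"{name:>12}: critical p = {cal.critical_p:.2e}, "
          f"{cal.n_significant:>4} declared, "
          f"estimated FDR = {cal.estimated_fdr:.3f}, "
          f"realized FDR vs truth = {fdr:.3f}")

# The mitigated (cdna) protocol affords a far laxer critical p and hundreds
# of discoveries; the artifact-laden protocols must calibrate to such strict
# thresholds that almost nothing passes — the realized FDR stays below the
# 0.1 target in all arms.
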