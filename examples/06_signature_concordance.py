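"""Compare signed gene signatures from two independent experiments.

Derives a brain-vs-liver signature from each of two simulated replicates
of the cDNA protocol (shared ground truth, independent noise), then
measures identifier overlap, direction concordance with a Fisher exact
test, and the correlation of the estimated log2 ratios.
"""


from globinbench import (default_design, default_profiles,
                         direction_concordance, generate_expression,
                         overlap_fisher, ratio_correlation, ttest_per_gene)


def signature_from(seed):
    design = default_design(1, protocols=("cdna",))
    expr, _ = generate_expression(design, default_profiles()["cdna"], 5000,
                                  seed=seed, structure_seed=99)
    stats = ttest_per_gene(expr, design.tissues)
    hits = stats[stats["p_value"] < 1e-3].copy()
    hits["direction"] = hits["effect"].map(lambda e: "up" if e > 0 else "down")
    return hits.rename(columns={"effect": "log_ratio"}), stats


sig_a, stats_a = signature_from(seed=10)
sig_b, stats_b = signature_from(seed=11)
print(f"signature A: {len(sig_a)} genes; signature B: {len(sig_b)} genes")

universe = set(stats_a["gene_id"])
overlap = overlap_fisher(set(sig_a["gene_id"]), set(sig_b["gene_id"]), universe)
print(f"overlap: {overlap.n_matched} shared genes, "
      f"Fisher exact p = {overlap.fisher_p:.2e}")

conc = direction_concordance(sig_a, sig_b, p_threshold=1.0)
print(f"direction concordance: {100 * conc.concordant_fraction:.1f}% of "
      f"{conc.n_matched} shared genes, Fisher p = {conc.fisher_p:.2e}")

r, n, _ = ratio_correlation(stats_a.set_index("gene_id")["effect"],
                            stats_b.set_index("gene_id")["effect"])
print(f"log2-ratio correlation over all {n} genes: r = {r:.2f}")

# Independent replicates of the same planted biology recover overlapping
# signatures agreeing in direction for essentially every shared gene, with
# a vanishing Fisher p — the signal is reproducible, not noise.
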