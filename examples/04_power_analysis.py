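"""Analytic and Monte-Carlo power for detecting a 1.4-fold change.

Power of the pooled two-sample t-test with 4 samples per group at
alpha = 0.01, for the three protocol noise levels (log2-scale SDs), plus
the per-group n needed to reach 90% power.
"""

from globinbench import PowerSpec, mc_power, power_t_test, required_n

print("n=4/group, 1.4-fold, alpha=0.01, two-sided:")
for name, sd in (("no_treatment", 0.36), ("pna", 0.30), ("cdna", 0.12)):
    spec = PowerSpec(n_per_group=4, sd=sd, fold_change=1.4, alpha=0.01)
    analytic = power_t_test(spec)
    mc, se = mc_power(spec, n_sim=100_000, seed=4)
    n90 = required_n(sd, 1.4, 0.01, 0.90)
    print(f"  {name:>12} (sd={sd:.2f}): power = {analytic:.3f} "
          f"(Monte Carlo {mc:.3f} +/- {se:.3f}), "
          f"n per group for 90% power = {n90}")

# Only the low-noise cDNA regime reaches 90% power at n=4; the noisier
# protocols sit near 10-20% and need several-fold more replicates to
# detect the same 1.4-fold change.
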