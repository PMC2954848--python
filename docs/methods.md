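# Methods

## The generative model

The synthetic-data generator emulates a controlled spike-in experiment:
a fixed Jurkat RNA background supplemented with a globin-message gradient
(0, 2, 4, 8% by mass) and a 1% brain or 1% liver tissue spike that acts as
a known differential signal, processed under one of three protocols. Each
gene's log2 intensity is

    x_gj = mu_g + alpha * beta_g * f_j + delta_g * 1[tissue_j = brain] + eps_gj

- `mu_g ~ Uniform(4, 12)` — baseline log2 intensity, spanning the usual
  microarray dynamic range.
- `beta_g` — globin-artifact slope, log2 units per unit globin mass
  fraction. 35% of genes receive a positive slope and 15% a negative one
  (the negative minority mimics how quantile-style normalization
  compensates strongly globin-responsive genes); the remaining half are
  unaffected. Magnitudes are LogNormal(ln 40, 0.5²).
- `alpha` — protocol artifact susceptibility: 1.0 (no treatment),
  0.7 (PNA blocks ~30% of the interference), 0.03 (cDNA amplification
  removes over 90%).
- `delta_g` — planted brain-minus-liver effect for a 5% subset of genes,
  Normal(0, 0.5²) resampled until |delta| ≥ 0.2 log2 units.
- `eps_gj ~ N(0, sigma²)` — homoscedastic log2-scale noise with protocol
  sd 0.36 / 0.30 / 0.12. Only a single per-protocol variance statistic is
  available for calibration (the mean SD of globin-correlated genes), so
  one global sigma per protocol is the faithful minimal choice.
- Globin enters linearly in the mass fraction: no dose-response shape is
  documented for the artifact, and linearity is the minimal model
  consistent with "correlated to the spiked amount".

Randomness flows from a single integer seed through two named child
streams — gene-level structure (mu, beta, delta, assignments) and
measurement noise — so `structure_seed` can pin the ground truth while the
noise varies. No global RNG state is touched.

### Calibration of the free parameters

Two generator parameters are not directly published and were fixed once,
from observed qualitative behavior of the benchmark's data:

- The slope-magnitude scale (LogNormal ln 40, sigma 0.5) is set so that in
  the untreated arm (alpha = 1, sigma = 0.36, n = 8) close to half of all
  genes pass the p < 0.01 correlation cut, matching the observation that
  nearly 50% of probesets correlate significantly with globin addition.
  A consequence is that the simulated untreated/cDNA artifact-count ratio
  (~20-30x) is larger than the ~13x seen on the real platform; only the
  ordering and a ≥5x separation are treated as meaningful.
- The cDNA susceptibility alpha = 0.03 sits inside the documented "more
  than 90% reduction" bound and is small enough that the residual globin
  variance falls below the planted tissue-signature variance. That
  inequality is what the benchmark's PCA observation pins down: for cDNA
  data the leading principal component is the brain/liver signature, with
  globin relegated to PC2. A susceptibility near the 0.1 edge of the bound
  would contradict that observed flip, so the smaller value is the one
  consistent with all reported behavior.

### What the generator does not emulate

Probe-level structure (PM/MM pairs, CEL images), RMA normalization itself
(values are emitted already normalized), intensity-dependent variance,
gene-gene correlation beyond the shared globin/tissue factors, and
scanner or batch effects. Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated under the benchmark's
statistical structure — not that any particular laboratory protocol will
achieve these numbers on real blood.

## Artifact quantification

Per-gene Pearson correlation `rho` against the per-sample globin fraction;
two-sided p-values from the exact t-transform `t = rho*sqrt(n-2)/
sqrt(1-rho²)` with n-2 degrees of freedom. The artifact rule is
`p < 0.01 AND |rho| > 0.6`, both thresholds exposed as parameters: the
magnitude cut and the p cut coincide only at a specific sample size
(p < 0.01 corresponds to |rho| > 0.834 at n = 8 and to ≈ 0.62 at n = 16),
and the implementation deliberately takes no position on which n the 0.6
figure presumed. Two-sided p-values are used throughout since the rule is
stated on |rho|.

Constant genes are reported with `rho = NaN`, `p = 1`, flagged
`constant_gene` — never silently dropped, and never artifact members even
under degenerate thresholds. Artifact amplitude is the mean across-sample
SD (denominator n-1) of the artifact genes; SD rather than covariance
keeps the quantity on the log2 scale of Cohen-style effect sizes.
Intensity densities are binned at 0.25 log2 units by default with strict
local-maximum peak detection and no smoothing — the simplest reproducible
reading of a density plot.

## Discovery and FDR calibration

Pooled-variance (Student) t-tests per gene; the generator's noise is
homoscedastic, making this the faithful minimal choice (Welch is an
option). Effects are reported as the alphabetically-first group minus the
other, i.e. brain minus liver.

The permutation null enumerates *balanced* unordered two-group partitions:
each pseudo-group holds equal numbers of brain- and liver-spiked samples.
For the default 4+4 design this gives exactly C(4,2)·C(4,2)/2 = 18
partitions, enumerated exhaustively; larger designs are sampled uniformly
without replacement under a seed once the count exceeds
`max_permutations`. Balance removes the true tissue contrast from the
null while leaving the globin artifact free to generate false positives
(the permuted groups are no longer globin-balanced), which is precisely
why artifact-laden protocols calibrate to stricter critical p-values.
Only tissue balance is enforced; no further stratification by globin
level is applied.

The FDR estimate at a threshold is the standard permutation plug-in:
mean null detections divided by observed detections (at least 1), capped
at 1. Calibration scans a descending grid (25 log-spaced points, 0.05 down
to 1e-6 by default) and returns the largest threshold meeting the target;
if none does, the smallest grid point is returned flagged `achieved=False`.
Estimating the null from all genes (including true positives, which the
balanced permutation largely neutralizes) makes the estimator
conservative, which the acceptance suite confirms against planted truth:
the mean realized FDR at target 0.1 sits near 0.07-0.08.

The ROC-style curve reports, per p-value threshold, total observed
detections against the permutation-mean false positives — both monotone
in the threshold by construction.

### Time-dose ANOVA

For ex vivo dosing experiments (vehicle / 0.33 / 3.3 uM drug at 0/3/6 h in
the default layout) each gene gets a joint fixed-effects F-test on all
dose-involving terms — dose main effect plus dose x time interaction —
against the within-cell error, equivalent to comparing the full two-factor
model with a time-only model. The closed-form balanced sums of squares are
vectorized across genes (per-gene OLS fits would be orders of magnitude
slower at 10^4 genes) and verified against statsmodels on fixtures. The
design must be balanced with at least two replicates per cell: with one
replicate the interaction-inclusive model leaves zero error degrees of
freedom, so such designs are rejected rather than silently refit. The
direction label is "up" when the top dose exceeds vehicle at the final
time — a convention, stated rather than inferred.

## Power

Exact power of the pooled two-sample t-test from the noncentral t
distribution with `df = 2n-2` and noncentrality
`|log2(FC)|/sigma * sqrt(n/2)`; two-sided by default. At the benchmark's
reference spec (n = 4/group, 1.4-fold, alpha = 0.01) this yields 0.93 /
0.19 / 0.13 for sigma = 0.12 / 0.30 / 0.36 — consistent with the
published 90% / 18% / 11% within rounding. The published claim that
raising n from 4 to 9 restores power for the noisier arms is not
reproducible under any single consistent setting (two-sided sigma = 0.30
needs n = 14); the package reports what the noncentral t gives.
`required_n` inverts the power function by scanning n upward;
`mc_power` provides a seeded Monte-Carlo estimate with binomial standard
error, used as an independent oracle in the tests (the analytic path is
additionally checked against direct numerical integration over the
pooled-variance chi-square). The far tail of scipy's noncentral t can
underflow to NaN at large noncentrality; the negligible opposite tail is
then dropped and a normal approximation backstops a fully degenerate
evaluation.

## PCA attribution

Samples are observations, genes variables; genes are centered but not
scaled — unit-variance scaling would erase exactly the amplitude
information the artifact carries. Components come from the full SVD;
variance fractions are the eigenvalue shares. Attribution correlates each
component's sample scores with the globin fraction and the brain
indicator and labels the component by the larger magnitude, making the
label invariant to component sign. The benchmark's qualitative signature
is the PC1 flip: globin-driven for the untreated arm, tissue-driven after
cDNA mitigation. Whether published variance shares (70%/10%) were pooled
or per-protocol is not documented; simulated shares are reported per
protocol and land near 92%/2% (untreated) — the ordering, not the share,
is the tested property.

## Concordance

Identifier matching is case-insensitive with duplicates collapsed to the
smallest-p entry (a deliberate reduction of platform-specific
probe-to-gene "best match" procedures, which need array annotation this
package does not model). Direction concordance counts agreement of
up/down calls over shared genes passing an observed-p threshold
(threshold ≥ 1 keeps all matched genes — both published denominators,
"significant genes only" and "without statistical cuts", are reachable
this way); significance of the 2x2 direction table and of set overlaps
uses the two-sided Fisher exact test under the standard "sum of tables at
most as probable as observed" rule. Note a subtlety of that rule: two
identical 10-gene sets in a 20-gene universe give p = 2/184756, not
1/184756 — the mirror table is equally improbable and is included.

## Problem sizes and determinism

Default analyses run at 20,000 genes x 8 samples; the acceptance checks
use 25 replicates for FDR control and 20 seeds for the ordering and PCA
properties, sizes at which every check completes in seconds to a few
minutes on a single core. All stochastic steps take explicit integer
seeds; the end-to-end benchmark report is byte-identical for a fixed
config and seed.

## Known limitations

- Slope magnitudes and the cDNA susceptibility are calibrated to
  qualitative published behavior (see above); absolute simulated counts
  are not expected to match platform-specific published counts, and real
  probe-level counts cannot be reproduced because the underlying arrays
  were never deposited.
- The homoscedastic noise model understates the intensity-dependent
  variance of real arrays; FDR conservatism observed here need not
  transfer to heteroscedastic data.
- With only 18 balanced permutations in the 4+4 design, the FDR estimate
  has coarse resolution at very small thresholds; calibrated thresholds
  are therefore grid-quantized.
- The ANOVA requires balanced cells; unbalanced ex vivo designs would
  need a regression-based (type-II/III) formulation that is out of scope.
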