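# globinbench

Spike-in benchmarking of globin-transcript interference in whole-blood
gene expression profiling.

Whole blood is the most accessible tissue for expression-based biomarker
discovery, but reticulocyte globin mRNA — up to ~70% of the message in a
whole-blood extract — cross-hybridizes promiscuously on microarrays and
drowns small biological signals. `globinbench` implements, as a reusable
and tested Python library, the quantitative machinery of a controlled
spike-in benchmark for this problem: a cell-line background (Jurkat) is
supplemented with a gradient of globin message (0/2/4/8% by mass) plus a
small tissue spike (1% brain or 1% liver RNA) that serves as a known
differential signal, and three sample-processing arms are compared — no
treatment, PNA globin blocking, and cDNA (Ribo-SPIA) amplification.

Because no public expression data accompany this design, the package ships
a first-class synthetic-data generator with known ground truth, emitting
log2 matrices with the benchmark's statistical structure:

```
x_gj = mu_g + alpha * beta_g * f_j + delta_g * 1[tissue_j = brain] + eps_gj,
eps_gj ~ N(0, sigma^2)
```

with per-gene baseline `mu_g`, globin-artifact slope `beta_g` (positive
majority, negative minority), planted brain-minus-liver effect `delta_g`,
per-sample globin mass fraction `f_j`, protocol artifact susceptibility
`alpha` (1.0 / 0.7 / 0.03) and protocol noise sd `sigma` (0.36 / 0.30 /
0.12 log2 units).

On top of the generator sit the benchmark's analyses:

- **artifact quantification** — per-gene Pearson correlation to the globin
  fraction with the `p < 0.01 and |rho| > 0.6` artifact rule, the analytic
  critical correlation (`|rho| > 0.834` at n = 8, p < 0.01), artifact
  amplitude as mean per-gene SD, correlation histograms, intensity-density
  profiles with peak detection;
- **differential discovery** — pooled-variance t-tests between tissue
  spikes, with the critical p-value calibrated to a false discovery rate
  target by a *balanced* permutation null (every pseudo-group holds equal
  numbers of brain and liver samples, so tissue signal vanishes while the
  globin artifact still inflates the null), ROC-style detection curves, and
  a joint time x dose ANOVA for ex vivo drug-dosing experiments;
- **power analysis** — exact noncentral-t power and sample-size inversion
  for two-group log2 fold-change detection, with a Monte-Carlo
  cross-check: noncentrality `log2(FC)/sigma * sqrt(n/2)`, `df = 2n - 2`;
- **variance decomposition** — gene-centered PCA with attribution of each
  component to globin amount or tissue by score-covariate correlation;
- **signature concordance** — case-insensitive identifier matching, signed
  direction concordance with exact Fisher tests, set-overlap significance,
  and log2-ratio correlation between analyses.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_fdr_calibrated_discovery.py` simulates all three
protocol arms at 20,000 genes (5% planted differential genes) and
calibrates discovery at FDR 10%:

```
no_treatment: critical p = 5.78e-05,    8 declared, estimated FDR = 0.097, realized FDR vs truth = 0.000
         pna: critical p = 1.42e-04,   21 declared, estimated FDR = 0.090, realized FDR vs truth = 0.048
        cdna: critical p = 3.34e-03,  697 declared, estimated FDR = 0.095, realized FDR vs truth = 0.077
```

Reading the rows: the globin artifact forces the unmitigated protocols to
calibrate to critical p-values two orders of magnitude stricter, leaving
them a handful of discoveries, while the cDNA arm declares ~700 of the
1,000 planted genes; in every arm the realized FDR measured against the
planted truth stays below the 0.1 target — the calibration is honest.
`examples/04_power_analysis.py` prints the matching power story (0.13 /
0.19 / 0.93 at n = 4 per group for a 1.4-fold change at alpha = 0.01) and
`examples/05_pca_attribution.py` shows PC1 flipping from the globin
gradient (92% of variance, untreated) to the tissue signature (cDNA).

A command-line interface mirrors the stages
(`globinbench simulate|artifact|de|roc|anova|power|pca|concordance|benchmark`);
`globinbench benchmark --seed 3 --out report/` writes the full
per-protocol summary table as JSON and TSV.

## Layout

```
src/globinbench/   containers, simulate, artifact, discovery, power,
                   decomposition, concordance, io, benchmark, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property, and acceptance tests)
docs/methods.md    model, assumptions, parameter choices, limitations
```
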