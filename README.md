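# mtrc — mixed-tissue ratiometric control benchmarking for expression microarrays

Clinical laboratories running gene-expression microarray assays need
objective, repeatable benchmarks of technical performance: can the assay
detect a true 1.5-fold change, and over which part of the intensity scale
are comparative measurements trustworthy? A **mixed-tissue ratiometric
control (MTRC)** answers both questions with two samples (Mix1 and Mix2)
built from the same 3–4 human RNA components — e.g. Universal Human
Reference RNA (UHRR), Human Brain Reference RNA (HBRR), liver RNA and
skeletal muscle RNA — combined in defined mass ratios. Probes selectively
expressed in one component then carry a *known* expected fold change
between the mixes, giving hundreds of built-in true positives and true
negatives that span the array's dynamic range.

This package implements the complete computational side of that method,
plus a ground-truthed simulator so the pipeline is testable without any
array data:

* **Analyte selection** — the tissue-selective index
  `TSI(p, t) = log2 signal of probe p in tissue t − max over the other tissues`,
  averaged over replicate datasets; probes with mean TSI > 3.22 log2 units
  (≈ ten-fold) become MTRC analytes with target log2 ratio
  `log2(mass in Mix1 / mass in Mix2)` (0.585 for a 1.5:1 component, −2 for
  1:4, 0 for the 1:1 reference).
* **Normalization** — per technical replicate, Mix2 is shifted by the
  difference in the 10% trimmed mean of the reference-component analytes
  between Mix1 and Mix2.
* **Diagnostic performance** — one ROC curve per fold-change subset
  against the reference analytes as true negatives. Singlicate assays rank
  by log2 ratio; replicate assays rank by paired t-test p-value. AUC is
  trapezoidal (equal to Mann–Whitney `U/(n_tp·n_tn)` with ties = ½), with
  Hanley–McNeil standard errors and z tests for AUC differences, plus
  pairwise Spearman concordance of replicate ratios.
* **Reliable range of measurement** — per analyte, the log2 ratio
  deviation `LRD = R_observed − target`; analytes rank-ordered by mean
  intensity `I` are cut into ~equal bins and each bin is tested with
  `chi2 = Σ LRD² / s²` against the chi-square quantile at α = 0.01, where
  `s` is the sd of log2 ratios over *all* probes. The longest run of
  contiguous passing bins is the reliable range — the linear region of the
  dynamic range, bounded below by background noise and above by signal
  saturation (ratio compression).
* **Simulator** — four-tissue selective expression, defined mixing
  ratios, replicate log-normal noise, and dynamic-range compression via an
  additive background floor plus a hard saturation ceiling, all with known
  ground truth.

## Worked example

```python
import mtrc

design = mtrc.MixtureDesign.mtrc4()          # UHRR 20/20, liver 30/20, HBRR 40/20, muscle 10/40 ug
config = mtrc.SimulationConfig(seed=42)      # 22,277 probes, floor at log2 6, ceiling at 14, sd 0.15
matrix, analytes = mtrc.simulate_mix_experiment(config, design, n_replicates=3)

results = mtrc.MtrcBenchmark(matrix, analytes, design).fit()
print(results.summary())
```

prints

```
MTRC benchmark results
======================
design: MTRC-4    mode: replicate    probes: 22277    analytes: 1035
reference component: UHRR    replicate pairs: 3

Normalization offsets (log2, added to Mix2):
  replicate 1: -0.0123
  replicate 2: +0.0010
  replicate 3: -0.0073

Diagnostic performance (ROC AUC vs the 1:1 reference analytes):
  subset              n_tp  n_tn     AUC      SE
  4-fold               154   197   0.934  0.0147
  2-fold               429   197   0.856  0.0145
  1.5-fold             255   197   0.798  0.0205

Pairwise AUC comparisons (independent z test):
  4-fold vs 2-fold: z = +3.75, p = 0.000175 **
  4-fold vs 1.5-fold: z = +5.40, p = 6.53e-08 **
  2-fold vs 1.5-fold: z = +2.33, p = 0.0196 *

Replicate ratio concordance (Spearman rho): 0.835 +- 0.008

Global log2-ratio sd over all probe sets: s = 0.199
Reliable range: [8.69, 13.11] log2 units (length 4.42, 7 bins, analyte coverage 35.1%)
```

Reading the output: the three fold-change subsets are ranked exactly as
the method predicts — 4-fold changes are easiest to detect (AUC 0.934)
and 1.5-fold changes are the most noise-sensitive (AUC 0.798), with the
differences statistically significant. The simulated compression (additive
background at log2 intensity 6, saturation at 14) shortens the reliable
range to the central [8.69, 13.11] window; only 35% of the analytes fall
inside it, flagging a dataset that would benefit from protocol
optimization. `results.plot_ri()` and `results.plot_lrd()` draw the
ratio–intensity and binned-deviation plots; `results.save_report(dir,
plots=True)` writes TSV + JSON reports.

The same operations are available from a thin CLI:

```sh
mtrc simulate --design design.toml --reps 3 --seed 17 \
     --out-matrix sim.tsv --out-analytes truth.tsv
mtrc report --matrix sim.tsv --roles sim.tsv.roles.toml \
     --analytes truth.tsv --design design.toml --out report/ --plots
```

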