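# Methods

This note documents the models, conventions and numerical choices behind
the `mtrc` package, in the order the pipeline runs.

## Mixture designs and target ratios

A design is a list of components with masses (μg) in Mix1 and Mix2;
exactly one component must have equal masses (the 1:1 reference). The
canonical four-component design mixes UHRR 20/20, liver 30/20, HBRR
40/20 and skeletal muscle 10/40 μg per 100 μg; the three-component
variant mixes HBRR 25/25, liver 45/30 and skeletal muscle 30/45 μg. A
component's target log2 ratio is `log2(mass_mix1 / mass_mix2)` — 0.585,
1, −2 and 0 for the four-component design; ±0.585 and 0 for the
three-component one. Scaling all masses by a common factor changes
nothing; reciprocal mass pairs give exactly opposite targets.

An optional per-component `mrna_fraction` weight models the fact that
cell-line-derived total RNA (UHRR) carries a larger mRNA fraction than
tissue RNA. With non-unit weights the target is computed on the weighted
mass of the component *relative to the reference component* in each mix.
This formulation was chosen over normalizing by the weighted mix total
because it (a) keeps the reference target at exactly 0 whatever the
weights, (b) reduces to the plain mass ratio at unit weights, and (c) is
what reference-anchored normalization actually measures. Default weights
are 1, reproducing the plain mass-ratio targets; the weighting is an
extension and no quantitative weights are prescribed.

## Analyte selection

`TSI(p, t) = log2 signal(p, t) − max over t' ≠ t of log2 signal(p, t')`,
computed per replicate dataset and averaged arithmetically. Selection
uses a strict inequality `mean TSI > cutoff` with cutoff 3.22 log2 units
by default (just under exactly ten-fold, which would be 3.32; the cutoff
is an exposed parameter). There is no secondary filter on absolute
intensity. Because
the TSI compares a tissue against the maximum of the others, at most one
tissue per probe can exceed any positive cutoff, the selected count is
non-increasing in the cutoff, and per-array constant shifts cancel.

Design reduction re-computes the TSI among the remaining tissues after
omitting one; since the competing maximum can only drop, the reduced
selection is always a superset of the full selection restricted to the
remaining tissues.

## Normalization

Per technical replicate, `offset = trimmed_mean(Mix1 reference analytes)
− trimmed_mean(Mix2 reference analytes)` is added to every Mix2 probe.
"10% trimmed mean" trims `floor(0.10 · n)` observations from each tail —
the most common convention; the convention is not fixed by the source
procedure, so a total-fraction mode (`floor(0.05 · n)` per tail) is
selectable. Mix1/Mix2 arrays are paired strictly by replicate index. The
correction is idempotent and depends only on the reference analytes.

## Diagnostic performance

The reference component's analytes are the true negatives of every ROC;
each fold-change subset supplies the true positives for its own curve.

* Singlicate ranking: normalized log2 ratio. In the default "signed"
  mode a true positive's score is its ratio times the sign of its target
  (a 4-fold-down analyte measured on target must outrank the true
  negatives); true negatives keep the raw ratio. An "absolute" mode
  (|ratio| for both classes) is available. The choice matters only for
  down-regulated subsets.
* Replicate ranking: two-sided paired t-test on the per-replicate
  Mix1 − Mix2 differences; the score is −p with no direction gating.
  Degenerate probes get sentinels chosen to preserve ranking semantics
  on noiseless data: all-zero differences → p = 1, constant nonzero
  differences (infinite t) → p = 0. Per-probe p-values are ranking
  scores, not inference outputs, so no multiple-testing correction is
  applied.

ROC curves are built by sweeping score thresholds with tied scores
collapsed into a single step; the trapezoidal AUC then equals the
Mann–Whitney statistic with tied pairs counted ½ (property-tested
against exhaustive pair enumeration). Standard errors use the
Hanley–McNeil formula with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`. AUC
differences are tested with `z = (A1 − A2)/√(SE1² + SE2²)` assuming
independent curves; the correlated-curves variant needs the rank
correlation between the two scoring runs, which this procedure does not
retain — a known limitation that makes the test slightly conservative
for curves sharing the same true-negative set.

Reciprocal (±τ) true-positive subsets, as in the three-component design,
are reported both combined into one ROC and per direction.

Replicate concordance is the mean ± sd (n−1) of all pairwise Spearman ρ
between per-replicate analyte log2-ratio vectors (average ranks on ties).

## Reliable range

With replicate-averaged normalized signals, `R = mean(Mix1) − mean(Mix2)`
and `I = (mean(Mix1) + mean(Mix2))/2` per probe. Each analyte's log2
ratio deviation is `LRD = R − target`. Non-reference analytes are
rank-ordered by `I` (ties broken by probe id for determinism) and cut
into `n_bins` (default 20) bins:

* `merge_low` (default for ≥ 4-component designs): the upper bins share
  the size `round(n / n_bins)` and the lowest-intensity bin absorbs the
  remainder — 838 analytes give 19 bins of 42 plus a low bin of 40;
* `omit_low` (default for smaller designs): the `n mod n_bins`
  lowest-intensity analytes are dropped and all bins are equal — 565
  analytes give 20 bins of 28 with 5 omitted.

Each bin is tested with `chi2 = Σ LRD² / s²` against the upper
chi-square quantile at α (default 0.01), where `s` is the sample sd of
`R` over **all** probes on the array (not only analytes). The
variance-ratio form with df = n is the standard goodness-of-fit
statistic for comparing a bin's deviations to a global noise estimate;
df = n−1 is selectable. The statistic is invariant to rescaling LRD and
s together.

The reliable range is the longest run of contiguous passing bins (ties
prefer the higher-intensity run, since low-intensity noise is the usual
concern); its limits are the minimum member intensity of the first bin
and the maximum member intensity of the last bin in the run (bin-mean
limits are a configuration switch). Coverage is the fraction of the
analytes entering the LRD analysis (binned plus omitted, i.e. the
non-reference analytes) whose `I` lies inside the limits; the reference
component is excluded because the procedure itself excludes it from the
bins, and this makes the noiseless identity (all bins pass ⇒ coverage
exactly 1) hold by construction.

## The simulator

`SimulationConfig` defaults describe the emulated study: a
22,277-probe array; four components (UHRR, HBRR, liver, skeletal
muscle) with 197/429/255/154 planted selective probes respectively;
baseline log2 abundances uniform on [4, 17]; an additive background
floor at log2 level 6 and a hard saturation ceiling at 14 applied in
linear space (`observed = min(ceiling, floor + abundance)`); replicate
noise sd 0.15 log2 units, drawn as `sd · z` from per-replicate
sub-streams of one master seed so that adding replicates never changes
earlier ones and runs with different sd share the same noise shape.

Two planting schemes serve the two experiment types. Tissue profiles
plant a finite elevation: a selective probe sits exactly `delta`
(default 5) log2 units above its level in every other tissue, so its
TSI equals `delta` and threshold behavior is exact. Mix experiments
plant perfectly tissue-selective analytes (expressed in exactly one
component), so that without compression the observed log2 ratio equals
the design target identically — mix abundances are mass-fraction-
weighted sums of component abundances in linear space, making each mix
a convex combination of the tissue vectors. The optional broad-coverage
tissue (UHRR analog) additionally expresses, for each other tissue, a
set of would-be-selective probes just below their selective level
(`broad_margin`, default 1 log2 unit); these fail selection while the
broad tissue is present and appear once it is omitted, reproducing the
observation that omitting the broad component yields the largest
analyte set.

What the simulator does **not** model: probe-sequence and labeling-
chemistry effects, spatial artifacts, batch effects, probe-specific
affinity spread, or mRNA-fraction differences between components
(unless weights are set). Passing tests therefore demonstrate the
correctness and calibration of the *computations* under a clean
generative model, not the behavior of any particular laboratory
protocol on real arrays.

## Numerical conventions

* Files are UTF-8 TSV with '.' decimals and 6 decimal places; write→read
  is value-exact at that precision. Matrices are always log2 scale.
* Sample roles (mix, replicate) come from a TOML sidecar, never from
  column-name parsing.
* Noiseless, compression-free runs give AUCs exactly 1.0 and offsets
  exactly 0; LRD values are zero up to float rounding (~1e-15, from
  taking log2 of linear-space mixing products).
* A constant ratio vector makes `s` undefined and is rejected
  (constancy is checked exactly, not via `sd == 0`, which float rounding
  can miss).
* Problem sizes used in the shipped tests and the acceptance script are
  desk-scale (2,000–22,277 probes, 3 replicates, ≤ 20 seeds per
  experiment), chosen so the full suite runs in seconds while keeping
  the array-sized default for the headline runs.

## Known limitations

* The chi-square bin test detects compression only once a bin's rms LRD
  exceeds ≈ `s · √(χ²crit/n)`. Under the additive-background model the
  distortion grows gradually as intensity falls, so the estimated lower
  limit sits systematically above the background level itself (about
  1.5–2.5 log2 units for 2–4-fold targets at the default settings), and
  the upper limit sits below the saturation level by up to half the
  largest |target| (one channel saturates before the mean intensity
  reaches the ceiling). The reliable range is therefore a conservative
  *inner* estimate of the undistorted region — appropriate for its use
  as a benchmark — and should not be read as an estimator of the
  physical floor/ceiling locations.
* AUC comparisons ignore the correlation between curves sharing true
  negatives (see above).
* With very small analyte sets the `merge_low` sizing rule can leave the
  lowest bin much larger than the rest; `omit_low` is preferable there.
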