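# Methods

## Model and assumptions

Each probe's log2 expression in the control cohort is modelled as normal
with unknown mean μ and standard deviation σ, estimated per probe by the
control-group mean and the n−1 (sample) standard deviation. The estimator
choice matters: the control group is a sample from a population, not a
census, and the method is explicitly aimed at modest cohort sizes. A tested
individual's deviation is standardised, z = (E − μ̂)/σ̂, and referred to the
standard normal two-sided, p = 2·(1 − Φ(|z|)). Two-sided p-values are used
because a single p threshold must catch both over- and under-expression;
the fold-change sign carries the direction.

The fold-change is the plain difference of log2 values, foldC = E − μ̂.
Inputs are required to be normalised log2 intensities, so a foldC of 1 is a
2-fold linear change; thresholds like "fc > 1.75" are only meaningful on
this scale.

A call requires both gates strictly: adjusted p < p_threshold and
|foldC| > fc_threshold. Defaults are p 0.01 and foldC 1. Correction across
multiple testing is applied over the probes *within* each tested sample
(m = number of probes), as either Bonferroni min(1, p·m) or Storey
q-values. The alternative reading — correcting across samples within a
probe — is not implemented but the correction is a per-sample function, so
it remains switchable at the call site.

**Normality caveat.** The z-score is only calibrated if the control values
are close to normal, which is why a Lilliefors screen (Kolmogorov–Smirnov
with estimated mean/sd, via statsmodels, approximate p-values) is provided:
run it at α 0.05 with multiple-testing correction and treat flagged probes
with suspicion. Constant probes are degenerate distributions; they are
flagged non-normal with p reported as 0 rather than crashing the screen.

**Known finite-sample limitation.** With an estimated μ̂ and σ̂ from n
controls, the null distribution of z is a scaled Student t (factor
√(1+1/n), n−1 df), not N(0,1). At n = 50 the nominal two-sided p < 0.01
gate therefore fires at a true per-test rate of
2·T₄₉(2.576/√1.02) ≈ 0.0139, not just under 0.01. This inflation is
inherent to the method's definition (the published statistic is the plain
normal z, not a t), shrinks like 1/n, and is negligible for cohorts of a
few hundred controls. It is the reason the benchmark AUCs below are ~0.999
rather than exactly 1: background probes accumulate slightly more chance
calls than the nominal rate predicts.

## Comparison modes and leave-one-out

The tested side and reference side are chosen from five modes
(test-vs-control, test-vs-all, test-vs-test, control-vs-control,
control-vs-all). Whenever a tested sample is itself a member of the
reference set it is removed from μ̂ and σ̂ before scoring: otherwise an
extreme sample inflates its own σ̂ and masks itself. The reference must
retain at least two samples after exclusion.

Degenerate σ̂ = 0 (a probe constant across the reference) yields z = 0 when
the sample equals the reference mean and a signed infinity (p = 0)
otherwise; such calls carry an explicit flag in the output tables.

## The simulator

The simulator emulates the validation design used to benchmark the
detector: a probes × samples grid (default 20,000 × 100, split 50 control /
50 experimental) of i.i.d. standard-normal values. Per direction,
`n_outlier_genes` probes are drawn without replacement (up and down sets
disjoint); each spiked probe gets a uniform 5–10 affected experimental
samples; each affected cell's value is **replaced** by
sign·Φ⁻¹(1 − p*/2) for a target tail probability p* drawn from
[10⁻⁶, 0.05]. Because the true background is exactly N(0,1), the injected
value *is* the population z-score and its two-sided tail p against the true
null equals p* exactly.

Open choices, fixed as follows:

* **p\* sampling** is log-uniform over the 4.7 decades of the range
  (uniform sampling would concentrate nearly all spikes at the weak end
  near 0.05); a plain uniform sampler is available as a named policy.
* **Two-sided magnitude mapping** (|z*| from p*/2), consistent with the
  detector's two-sided p-values; a one-sided reading would shift the
  weakest spikes from 1.96σ to 1.64σ.
* **Replacement, not addition**: the spec of the design is that the spiked
  value corresponds to a chosen tail probability, which only holds if the
  value itself encodes it.
* One seeded generator drives background, probe selection, sample
  selection and p draws in that fixed order, so datasets are bit-identical
  per (config, seed).

What the simulator does **not** emulate: probe–probe correlation, batch
effects, heteroskedastic or heavy-tailed probes, platform artefacts.
Passing benchmarks here show the detector's behaviour under its own model
assumptions; they do not certify calibration on real arrays (that is what
the normality screen is for).

## Benchmark and ROC construction

Detection for the benchmark uses raw p < 0.01 and |foldC| > 0.5 in
test-vs-control mode. Probes are ranked by the number of tested samples
called in the given direction (uncalled probes score 0); up-calls are
ranked against the up-spiked truth set and down against down. Because the
score is a small integer, ties dominate; the ROC threshold sweeps the
distinct score values so tie groups move as blocks, and the trapezoidal
area is then exactly the Mann–Whitney probability with ties counted ½ (the
test suite checks this against exhaustive pair counting and against
scikit-learn). Any within-tie ordering would be arbitrary and
irreproducible, so none is materialised. External scorers (e.g. a GTI
implementation) plug into the same ranking interface as a probe → score
mapping; no third-party outlier statistic is reimplemented here.

The headline quantities are the per-dataset AUCs over the sweep of spiked
gene counts (20, 50, 100, 250, 500, 1000 per direction) and their mean per
direction, averaged over the sweep; `scripts/acceptance.py` repeats the
sweep for three derived seeds and reports the mean up- and down-direction
AUC (typically ≈ 0.999 both ways at full scale). The averaging set is the
six sweep levels × three seeds.

**Problem sizes.** The acceptance script runs the full 20,000-probe sweep
(about 15 s per three-seed replicate set). The test suite exercises the
same property at 2,000 probes with sweep levels 10/25/50/100: the
count-ranking AUC property is scale-free in the probe dimension, and levels
below ~10 positives make a per-dataset AUC too granular to bound at the
0.005 resolution the tests use.

## Numerical choices

* Strict threshold comparisons (p < τ, |fc| > τ_fc), matching the
  convention "p<0.01, fc>1.75" used in reported tables.
* Storey q-values: π₀ estimated on λ ∈ {0.05, …, 0.95} with a cubic
  smoother evaluated at λ = 0.95, clipped to (0, 1]; a degenerate fit falls
  back to π₀ = 1 (Benjamini–Hochberg-equivalent). q-values are made
  monotone by a tail-side running minimum and never exceed Bonferroni.
* p = 0 on volcano plots is drawn at half the smallest positive p in the
  vector, keeping infinite points plottable without distorting ranks.
* Heatmap clustering: Euclidean distance, complete linkage; probe-only for
  per-individual heatmaps, both axes for the combined-cohort heatmap. A
  single-probe (or single-sample) axis skips clustering with a warning
  rather than failing.
* Expression TSVs are written with `%.17g`, so write→read round-trips are
  bit-exact; result tables use fixed formats (p scientific 4 significant
  digits, z and foldC 4 decimals) so repeated runs are byte-identical.
* Missing or non-numeric expression cells are rejected at load with their
  (probe, sample) coordinates — the statistics assume complete rows, and
  silent imputation would change μ̂ and σ̂ invisibly. Samples present in
  the design but absent from the matrix (or vice versa) are an error, not
  a silent drop.

## Limitations

* The plain parametric z is not robust: a contaminated control group
  inflates σ̂ and masks outliers (only self-referential modes get
  leave-one-out protection). Median/MAD variants are out of scope by
  design.
* Per-test false-positive calibration is approximate at small control
  sizes (see the Student-t note above).
* Group-vs-group differential expression is explicitly not this tool's
  job; it complements, not replaces, SAM-style analyses.
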