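# Methods

This note documents the models, estimators and numerical choices behind
`decayomics`, and what the synthetic experiment does and does not
capture about real rifampicin-chase microarray data.

## Decay model and estimation

Each transcript in each strain contributes twelve pooled points: three
biological replicates sampled on three different four-point schedules
(0/2/8/15, 0/5/10/18, 0/3/12/30 minutes after rifampicin), with the
three t = 0 arrays entering as three separate points. The base model is
first-order decay, estimated by ordinary least squares of
ln(intensity) on time; the degradation rate constant is k = −slope and
t½ = ln 2/k. Standard errors use the textbook OLS formula with
n − 2 degrees of freedom.

The delay model adds a transcription-arrest delay τ: a flat baseline up
to τ followed by exponential decay, continuous at the breakpoint
(a hinge regression on (t − τ)₊). τ is profiled over a grid (default 0
to 5 min in 0.1-min steps, constrained to at most half the chase
duration); the τ minimizing the residual sum of squares wins and ties go
to the smallest τ. The slope standard error is taken from the two-
parameter hinge design at the chosen τ with n − 2 df; the extra degree
of freedom spent on τ is ignored, which is the usual profiling
approximation.

**Identifiability of τ.** With only ~4 points at or before the typical
delay and multiplicative noise, the per-transcript RSS profile in τ is
nearly flat: individual τ̂ values scatter widely over the grid (mean
absolute error above 1 minute at the default noise) while the *cohort
mean* of τ̂ is unbiased to within ~0.1 min. Per-transcript delays should
therefore be read only in aggregate; `fit_delay_shared` pools the RSS
over a cohort and returns a far better-determined single τ̂.

**Reliability and detection.** A fit is *reliable* when the coefficient
of variation of the slope (SE/|slope|) is below 30% and k > 0. A fit is
*detected* when the transcript's mean T0 intensity exceeds 3× the
array background level, measured as the median intensity of the
rank-invariant probe set. The detection filter exists because a flat
background trace can pass the CV filter by chance with an arbitrary
apparent half-life; the pipeline's retained gene set (and the
"available in all strains" intersection) requires both flags.

## The two normalization paths

Decay and steady-state quantities need different treatment, and the
pipeline keeps the two routes strictly separate (each output carries a
path label):

* **Decay path** — probes are scaled between strains by the
  rank-invariant probe-set medians only, then summarized as the median
  of each transcript's 16 probes. Scale factors are constant within a
  strain (computed on its T0 arrays, applied to all twelve), so the
  slope of ln(intensity) versus time — the only decay-relevant
  quantity — is untouched; in the noiseless limit the round trip
  recovers k to machine precision.
* **Steady-state path** — T0 arrays get normexp background correction,
  quantile normalization within each strain's replicate triplet,
  invariant-set scaling between strains, and median-polish
  summarization on log2 intensities; linear-scale values are then
  multiplied by the strain's total-RNA extraction yield (µg RNA per mg
  dry cell weight; defaults 15.6/17.2/35.9 for control, RNase R and
  PNPase mutants) to give concentrations in AU per mg DCW that are
  comparable across strains with different total RNA content.

**Normexp correction.** The observed intensity is modeled as
X = S + B with signal S ~ Exp(α) and background B ~ N(µ, σ²); the
corrected value is the posterior mean
E[S | X = x] = m + σ·φ(m/σ)/Φ(m/σ) with m = x − µ − σ²/α, computed in
log space so deep-background values stay positive. Parameters are
estimated per array: µ as the mode of a smoothed intensity histogram
(refined by zooming, since intensities span decades while the
background peak is narrow), σ as the RMS spread below the mode, α as
the mean excess above it.

**Rank-invariant probes.** Probes qualify when their mean normalized
rank across the nine T0 arrays is in the bottom quartile and their rank
range is at most 0.05. These thresholds are configuration-exposed; on
default simulations they select a few dozen to a few hundred probes,
all sitting in the array background. Selection uses the nine T0 arrays
of all strains; the alternative reading (a single strain's twelve
arrays) is supported by passing a different array list.

**Median polish.** Per transcript, the probes × arrays log2 block is
decomposed into probe and array effects by alternately subtracting row
and column medians; the transcript's expression on an array is the
overall plus that array's column effect. The sweeps contract
geometrically (~0.8× per iteration), so iteration runs until the
largest subtracted median falls below 10⁻⁶ (cap 500 sweeps) — a cap of
~20 sweeps would leave the fit ~10⁻³ from its limit.

With only three arrays per condition, median polish has a genuine
estimator atom at "no array effect": about a third of residuals are
exactly zero after the row step, so for a sizeable fraction of
transcripts the three replicate values come out exactly equal. This
propagates into the differential-expression stage (below).

## Differential stability

The change in degradation rate between mutant B and control A is the
time×strain interaction b₃ in the pooled 24-point model
ln y = b₀ + b₁t + b₂S + b₃(t·S), S = 1{B}, tested two-sided on
n − 4 df. P-values are BH-adjusted across transcripts (threshold 10%);
a raw-p 0.05 classification mode produces the four-class cross-tab
(significant/not × destabilized/stabilized), where destabilized means
the half-life fold change t½(B)/t½(A) from the per-strain log-linear
fits is below 1 — classification is deliberately decoupled from the
test. Comparisons are pairwise per gene; a single all-gene model with
gene fixed effects was considered and rejected as both slower and
statistically equivalent under per-gene error variances.

Note one emulation artifact: the generator gives the RNase R mutant a
uniform ~17% rate decrease (so its median half-life is 28 min against
the control's 24, as a global distribution shift). Without biological
noise large enough to mask it, this shift is statistically detectable
on the fastest-decaying transcripts, so the synthetic RNase R mutant
shows a modest number of significant "stabilized" calls even though no
per-gene effect was planted; real culture-to-culture variability buries
such uniform shifts.

## Differential expression

Log2 concentrations of the T0 triplicates are compared by a moderated
t statistic: the pooled per-gene variance s² (d = n_A + n_B − 2 df) is
shrunk toward a prior s₀² with weight d₀,
s̃² = (d₀s₀² + d·s²)/(d₀ + d), and t = Δlog2 / (s̃·√(1/n_A + 1/n_B)) is
referred to a t distribution with d₀ + d df (normal limit when
d₀ = ∞). The hyperparameters are estimated by moment matching on
ln s²: the adjusted log-variances e = ln s² − ψ(d/2) + ln(d/2) have
mean ln s₀² and excess variance ψ′(d₀/2) beyond the sampling term
ψ′(d/2); d₀ comes from the trigamma inverse (Newton iteration) and
s₀² from exp(mean e). When the empirical variance does not exceed the
sampling term, d₀ = ∞.

Because of the median-polish atom, the pipeline's variance vector mixes
a well-behaved bulk with exact and near-zero values; the DE driver
therefore (a) restricts to genes detected above background in both
strains and (b) winsorizes ln s² at its 10%/90% quantiles before moment
matching. The winsorized d₀ is approximate (clipping deflates the
spread, inflating d₀) but anchors the shrinkage target at the bulk
variance scale; the bare estimator without winsorization retains the
exact moment-matching contract and its parameter-recovery behavior.

Significance uses BH-adjusted p < 1% together with a fold change above
2 or below 0.5, on the yield-scaled linear concentrations. Because the
yield multiplication is part of the measurement definition, a mutant
with more RNA per cell mass shows a genuine genome-wide "up" shift —
the synthetic PNPase mutant calls most detected genes up, which is the
intended behavior of the method, not an error.

ncRNA fold changes from count tables are (count_B/lib_B)/(count_A/lib_A)
with a 0.5 pseudo-count on zero counts; library sizes default to column
totals but should be supplied externally when composition effects are a
concern (a planted 7-fold effect on abundant features measurably
inflates total-count normalization). Enrichment is a one-sided
hypergeometric over-representation test at a 5% cut-off with
user-supplied category sets.

## Saturation phases

One point per retained (transcript, strain) pair at
(log₁₀ mean T0 concentration, log₁₀ k). Phases are found by k-means
(k = 3) on the pooled log-concentration values — Lloyd iterations with
k-means++ starts, 20 restarts, fixed seed (recorded in the manifest) —
and relabeled I/II/III in increasing concentration order; a 2-D mode
clustering (log conc, log k) jointly is available behind a flag.
Correlations are Pearson on the log-log coordinates with the t-based
two-sided p (n − 2 df); phases with fewer than three usable points
report no coefficient. Cross-strain membership is a 3×3 contingency
table over the common gene set.

## The synthetic experiment

The generator's defaults define the simulated study:

| parameter | default | rationale |
| --- | --- | --- |
| transcripts | 2000 (config) | desk-scale stand-in for ~4300 genes |
| probes/transcript | 16 | array design |
| schedules | 0/2/8/15, 0/5/10/18, 0/3/12/30 min | chase design |
| t½ distribution | lognormal, median 24 min, gsd 1.8, truncated to 4–60 min | stationary-phase medians; the 0–30 min design cannot resolve half-lives much beyond an hour, and unresolvable tails would dominate raw-scale recovery metrics |
| probe noise (ln sd) | 0.2 | per probe per array |
| biological replicate noise (ln sd) | 0.05 | per transcript per culture, shared across its four points; gives replicate variance a realistic floor |
| probe affinity (ln sd) | 0.15 | fixed per probe |
| background | additive N(50, 10), per-probe level factor ln sd 0.3, floored at 10⁻⁶ | matches the normexp generative form; the per-probe factor gives background probes the stable rank order that makes a rank-invariant set exist at all |
| unexpressed fraction | 0.35 | genes silent in late stationary phase; makes arrays background-dominated as real chips are, and reproduces a ~65% "available in all strains" fraction |
| concentration regimes | fractions 0.60/0.25/0.15; ln-centers 7.5/10.5/13.5, sd 0.5; within-regime corr(ln k, ln C) = −0.80/−0.65/0 | three-phase saturation structure; centers 6 sd apart so the regimes are separable concentration zones — closer centers let k-means boundary errors inject extreme-leverage log-k outliers into neighboring phases |
| mutant effects | PNPase mutant: 20% of transcripts destabilized (k × 2) and 10% differentially expressed (log2FC ± 2); RNase R mutant: uniform k × 24.2/28.3 | planted-recovery targets plus the observed global-shift behavior |
| delay τ | 0 min (config) | with/without-delay half-lives nearly coincide in the emulated setting; delay cohorts set τ = 2 explicitly |

In the substrate-limited and intermediate regimes, concentrations follow
ln C = a − b·ln k + ε with b and sd(ε) derived from the planted
correlation and the empirical sd of ln k; the saturated regime draws
ln C from the top band independently of k. The truncated-lognormal
location is calibrated (Brent root-find) so the truncated median equals
the configured 24 min.

**What the simulation does not capture.** No probe-sequence effects
beyond a static affinity, no scanner saturation, no spatial artifacts,
no cross-hybridization structure, no array-level scale drift (quantile
normalization and invariant scaling are therefore exercised as
consistency checks, not stress-tested), and mutant effects are planted
independently of the concentration structure — so mutant strains show
*diluted* within-phase correlations relative to the control, whereas in
real data regulatory coupling can preserve them. Passing recovery tests
on this generator demonstrates the estimators are correct under the
stated noise model, not that the noise model exhausts real microarray
pathology.

## Problem sizes and numerics

Test and acceptance cohorts use 500–2000 transcripts (30 000 for the
phase-structure sweep, truth-level), 200 replicate simulations for the
null calibration of the interaction test, and 10⁵ genes for
empirical-Bayes recovery — sizes at which every Monte-Carlo acceptance
margin is several standard errors wide. All randomness flows from
numpy `default_rng` seeded per stage; identical seeds give
byte-identical output trees (the run manifest records seeds, thresholds
and scale factors, and contains no timestamps). Intensities are floored
at 10⁻⁶ before logs; zero medians, empty invariant sets, degenerate
(constant) inputs and singular designs raise typed validation errors
naming the offending field.
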