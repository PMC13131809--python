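# Methods

This note documents the models, the synthetic-data conditions, the
numerical choices, and the open design decisions behind `ssdpriors`.

## Task structure and conditions

The saccadic suppression of displacement (SSD) grid couples two noise
manipulations that share one cell.  Image noise (probe width 0.5°, 1.25°,
2.0°; 1.75° as a configurable alternative for the high level) varies only
on with-saccade trials; saccade-driven noise is manipulated by removing the
intervening saccade at low image noise.  The four noise conditions are
therefore ordered `no_saccade, low, medium, high`, with `low`
(with-saccade, low image noise) the **common** reference condition.  Cued
priors are 0.2 and 0.8 everywhere, plus a 0.5 prior in the two
low-image-noise cells that is used for model fitting only.  Displacements
are N(0, 2.5²) deg on jump trials and N(0, 0.2²) on non-jump trials; sign
is stored but every model operates on |x| (both hypothesis distributions
are centered on zero, so the task is symmetric).  Sessions enter analysis
only with ≥ 10 valid trials per condition (≥ 5 zero-displacement trials
for the displacement-zero control); the hardware probe-timing check is
abstracted as a boolean `valid` flag.

## Bayesian ideal observer

The decision rule compares the squared percept to the criterion x̂_c²
(see README for the closed form).  Numerics: the report probability is the
noncentral-χ² survival function from SciPy (`ncx2.sf`); a non-positive
criterion returns probability exactly 1 (the posterior favors "jump" for
every percept — this regime occurs for strong jump priors and is
deliberately not an error).  `sigma_jump == sigma_nojump` makes the
criterion undefined and raises.  Inside the optimizer a mathematically
identical Gaussian-tail form Φ((x−x̂_c)/σ_t) + Φ((−x̂_c−x)/σ_t) is used for
speed; a unit test pins the two routes together at 1e−10.

Pure-observer simulations use σ_J = 5°, σ_¬J = 0.1° (no saccade) / 0.75°
(saccade) and σ_t = 0.4/0.65/0.9° for low/medium/high image noise, under
which prior use is monotone nondecreasing across the four conditions.  The
combined-model protocol instead uses σ_J = 2.5° — both parameterizations
are plain configs; they serve different illustrations and are not
reconciled further.

## Category-learning network

75 input units tile 0–7.5° in 0.1° bins; activation is a Gaussian density
evaluated at bin centers (not integrated over bins — negligible at 0.1°
bin width), truncated by discarding out-of-range mass and renormalizing to
sum exactly 1.  Zero encoding noise is the one-hot limit (also used as an
underflow fallback for widths far below the bin scale).  Displacements
beyond the range clamp to the boundary.  Weights start at 0.5 for every
connection (any symmetric positive constant is equivalent up to output
normalization; the constant is a config field) and updates are applied
unclamped, so weights may cross zero after heavy training; the normalized
output can then leave [0,1] slightly and is clipped at the point where it
enters the combined model.  Training encodes each trial and applies
Δw = β·a·(d−o) to the trial's prior bank only; the procedure is
deterministic given the trial stream (the seed argument exists for
interface uniformity).

## Combined model and simulation protocol

2000 trials per simulation: 1000 training trials in the with-saccade
low-image-noise condition with priors interleaved, then 1000 test trials
with frozen weights split uniformly at random over the 4 conditions × 2
priors (the protocol only fixes that test trials cover the grid).  Binary
responses are Bernoulli draws from O_C; the deterministic outputs are
retained alongside so tests can use the low-variance path.  Defaults:
w_B = 0.1, σ_J = 2.5°, σ_¬J = 0.5/1.0°, Bayesian σ_t = 0.1° in all
conditions, perceptron noise 0.1/1/2°, β = 0.5.  Prior use is the mean
response-rate difference between priors over |x| ∈ [0, 2]; an empty prior
cell in the window yields NaN with a warning, never a silent zero.
Session-level comparisons expose a paired t-test (no-saccade vs common), a
repeated-measures ANOVA over image-noise levels with pairwise paired-t
follow-ups; degenerate zero-variance inputs report t = 0 / F = 0 with
p = 1.

## Model fitting

Free parameters (12): per-condition image noise (enters the perceptron
encoding), per-condition saccade-driven noise (the Bayesian non-jump
width), σ_J, and three fitted priors.  The Bayesian component's perceptual
σ_t is pinned at 0.1° in every condition, mirroring the combined model's
division of labor between components.  This pinning matters: if the
per-condition image-noise parameter is shared with the Bayesian component,
the cued priors sit on a nearly flat likelihood ridge (moving them far from
the generating values changes the log-likelihood of a 2000-trial session
by only a few nats) and cannot be recovered; with the division of labor
they are identified by the sharp per-condition decision steps.

The perceptron component is instantiated from data: a cumulative Gaussian
in |x| with guess and lapse rates (bounds: midpoint 0–7.5°, slope
0.01–10°, guess/lapse 0–0.5) is fit per cued prior, its value at each bin
center defines that bin's jump weight (no-jump weight = 1 − value), and
with encoding noise the component output is the activation-weighted
average of the curve.  Degenerate all-same-response data yield a flagged
boundary fit.

Likelihood: Bernoulli over trials with probabilities clamped to
[1e−9, 1−1e−9]; proposals with σ_J ≤ max σ_¬J receive a large smooth
penalty instead of an error.  Optimization: L-BFGS-B within σ ∈ [0.01, 10]°
and priors ∈ [0.01, 0.99], one canonical start plus seeded random restarts
(log-uniform σ, uniform priors); all restart endpoints are returned.
w_B is fixed at 0.1 by default and overridable — whether it was free in
the original session fits is not documented, so it is treated as a config.

**Parameter recovery design.**  Because the fit re-estimates the
psychometric curves from the very responses being modeled, a recovery
ground truth whose curves differ from what refitting returns is
mis-specified by construction (the refit absorbs Bayesian structure and
biases the other parameters).  Recovery studies therefore generate data
with *self-consistent* curves: fixed points of the refit step, computed by
iteratively refitting cumulative Gaussians to the model's own mean output
over conditions, weighted by the task displacement density.  At the study
scale (10 sessions × 2000 trials, 6 restarts) the cued priors are
recovered with median absolute error ≈ 0.06 and correct rank order.

## Neural analyses

Epoch rates (count/duration over fixation 0–250 ms and reafferent
0–800 ms) feed all statistics; z-scoring (non-overlapping 20-ms bins
pooled over all conditions) and smoothing produce display series only.
"20 ms Gaussian kernels" is read as σ = 20 ms, truncated at ±3σ and
normalized to unit area.  The prior contrast uses the unpaired Wilcoxon
rank-sum (the trial groups are independent), with the tie-corrected normal
z and effect size z/√n, signed positive when high-prior rates are larger;
exact enumeration exists in the test suite as an oracle for small samples.
The epoch screen uses α = 0.025 (two epochs); sliding bins are 15
overlapping 100-ms windows over 0–800 ms at α = 0.025/15, reporting the
earliest significant bin.  Normalization to the common condition is a
ratio with floor ε = 0.01 on the denominator (sessions below the floor are
excluded from correlations).

**Mixed models.**  Fixed effects: prior (high-prior indicator), saccade
{0,1}, image noise {0,1,2}, |displacement|, and the three pairwise
interactions.  Because image noise varies only on with-saccade trials, the
image × saccade column is exactly collinear with the main effects under
any numeric coding; aliased columns are detected (greedy QR/rank test) and
dropped, and the design object reports them.  The linear rate model is
REML `MixedLM` grouped by neuron; the binomial response model is a
variational-Bayes binomial GLMM grouped by session; both default to random
intercepts plus an independent random slope for the prior.  Coefficient
"p-values" for the variational fit are normal approximations from the
posterior mean/SD.

**Pattern classification.**  The four qualitative outcomes are encoded as
gain templates over the condition order (common = 1): bayesian
(0.25, 1, 1, 1), anti-bayesian (1, 1, 0.55, 0.25), prior-only
(1, 1, 1, 1), output-mirroring tracks the behavioral prior-use profile.
A neuron's per-condition effect vector is first linearized — rank-sum
effects compress large rate differences, so each effect is mapped through
the common-language effect size to an equivalent normal shift,
d = √2·Φ⁻¹(e/√3 + ½) — then matched to each template under a free positive
scale; the smallest least-squares residual wins.  Template matching is
used instead of per-ratio thresholds because ratios to a noisy
common-condition denominator roughly triple the decision noise.  A common
effect below 0.05 in magnitude is "unclassified".

## Synthetic data

Neurons are inhomogeneous Poisson: base 20 spikes/s in all windows
(fixation −100..400, probe −100..500, reafferent −200..1000, response
−300..300 ms); within the reafferent 0–800 ms span, high-prior trials add
depth × gain(condition) with depth 5 spikes/s by default, and
|displacement| adds 1.5 spikes/s per degree (reafferent responses are
displacement tuned).  The modulation starts exactly at the reafferent
event and ends at +800 ms.  Negative programmed rates clamp at zero with a
warning.  Response latencies are drawn lognormal with median 611 ms and
only place the response event.  Behavioral sessions draw trial types
uniformly from the full grid, displacements from the cued mixture, and
responses from the combined model; optional logit offsets
(`behav_interactions`, coded relative to the common cell) deepen the prior
× saccade and prior × image interactions for studies that need behavior
with both effects strongly expressed — the default combined model produces
the right signs but a modest saccade effect.

What the generator does *not* emulate: non-Poisson spiking statistics,
rate autocorrelation, neuron-to-neuron correlation, drift within sessions,
receptive-field geometry, and realistic trial counts for the
classification study (see below).  Passing tests therefore demonstrate
correctness of the analysis chain and its calibration under the stated
generative conditions, not performance guarantees on real recordings.

## Study scales and calibration results

Chosen once as the package's study conditions:

* Monte-Carlo validation of the decision rule: 20 random settings × 1e5
  draws, agreement within 3 SE.
* Combined-model pattern: mean of 20 seeded simulations.
* Parameter recovery: 10 sessions × 2000 trials, 6 restarts (5 restarts
  and 8 sessions in the faster acceptance script).
* Null calibration: 1000 prior-ignorant neurons (600 in the script), 800
  behavioral trials, flag rates compared at 3 binomial SEs.
* Dissociation: 20 cohorts (10 in the script) of 12 sessions × 320 trials,
  one anti-Bayesian neuron per session, behavior with
  `behav_interactions = (2.0, −0.5)`.
* Classification: 200 neurons per pattern (150 in the script) on an
  8000-trial session with `behav_interactions = (5.0, −0.5)` so the
  behavioral profile expresses both effects (the output-mirroring pattern
  is only distinguishable when behavior itself is); several hundred trials
  per cell are required for ≥ 90 % per-pattern accuracy at depth
  5 spikes/s on base 20 — at realistic (tens of trials) counts the
  mirroring and anti-Bayesian patterns are statistically confusable, which
  is precisely why the regression dissociation exists.

## Known limitations

* The binomial GLMM is variational; its posterior SDs (hence p-values) are
  approximate.  The linear mixed model can sit at a variance boundary on
  small cohorts (reported via convergence warnings).
* The image × saccade interaction is structurally unidentifiable in this
  task grid; the package reports rather than resolves this.
* The fitted-curve instantiation of the perceptron during session fits is
  an interpretation (the procedure is stated only loosely in the source
  description); it is isolated in one function and documented.
* Sliding-bin tests on 100-ms Poisson counts lean on the normal
  approximation at heavily tied small counts; calibration at α = 0.025/15
  is verified empirically to within binomial error, but the approximation
  is slightly anticonservative in the extreme tail.
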