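# Methods

This note records the model, every tunable that matters, the design
decisions taken where the design was genuinely open, and what the synthetic
data can and cannot show.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and windowing

A *day-approach* sample is a 7×10 matrix: 7 consecutive days × 10 daily
load variables (counts, kilometres, hours, and three 0–10 perceived
ratings), labelled by injury on the prediction day (the day after the last
history row).  A contiguous block of d days yields d − 7 windows; gaps in
the day index invalidate windows that would span them.  Windows never cross
athletes.

**Normalization** is min-max within each athlete, per variable, over that
athlete's full available history; the same state is reused for later data
from the same athlete.  Constant variables map to 0 by convention.  Whether
the per-athlete extrema should instead come from a training period only is a
real alternative for deployment; here test athletes are disjoint from
training athletes, so each test athlete's own history is the only available
reference, and that is what the package uses.

**Padding** appends one time step (7 → 8) so that the auto-encoder's two
pool/upsample pairs round-trip the spatial size (8 → 4 → 2 → 4 → 8).  The
default replicates the last observed day (edge padding), which adds no
artificial discontinuity to the angular or recurrence encodings and leaves
every per-variable min/max unchanged; zero padding is available
(`pad_mode: zero`).

## Image encodings

All four encodings operate per variable on the normalized 8-step series,
giving an 8×8×10 stack per window.

* **GASF / GADF.**  θᵢ = arccos(x̃ᵢ) with x̃ clamped to [0, 1] to absorb
  floating error (values outside by more than 1e−9 raise instead — they
  signal missing normalization); rᵢ = tᵢ/N with tᵢ = i (1-based).  GASF is
  cos(θᵢ+θⱼ) (symmetric, diagonal cos 2θᵢ, so the original series is
  recoverable from the diagonal); GADF is sin(θᵢ−θⱼ) (antisymmetric, zero
  diagonal).
* **MTF.**  Q = 5 uniform-width bins over [0, 1] (the series is already
  normalized; quantile binning is a config option).  W is estimated from
  first-order transition counts with row normalization; bins never visited
  leave all-zero rows rather than uniform ones, so the matrix states exactly
  what was observed.  The field is Mₖₗ = P(next ∈ bin(xₗ) | current ∈
  bin(xₖ)); because the conditioning direction of a transition matrix is a
  pure convention, a `transpose` switch is provided.
* **RP.**  States are delay vectors; the default embedding is dimension 1,
  delay 1 — an 8-step series leaves no room for higher embeddings — both
  configurable.  The threshold ε defaults to 0.2 × the maximum pairwise
  state distance of the window (an ε must be chosen; a fixed fraction of the
  observed scale keeps the plot informative for every window), with a tiny
  positive floor so a constant series recurs everywhere.  The plot is binary
  with a strict inequality (distance < ε), giving a unit diagonal.

MTF and RP values in [0, 1] are affinely mapped to [−1, 1] before the
auto-encoder, whose output activation is tanh; GASF/GADF already live there.

## Three-step resampling

Operates on flattened 8×10 window features (80 values) *before* image
encoding, so synthetic samples are valid time series and the encodings'
structural invariants (MTF row-stochasticity, RP binarity) survive;
interpolating in image space would break them.

1. **Balanced per-athlete sampling.**  Every athlete with at least one
   injured and one uninjured window contributes exactly k of each (with
   replacement when fewer exist); athletes without injuries are excluded and
   logged.  Default k = ceil(mean injured windows per athlete among athletes
   with at least one) — the procedure fixes only the step-2 totals, so k is
   derived from the data and config-exposed.
2. **Controlled unbalanced subsampling.**  Exactly `n_injured_target`
   injured (default 650, a fixed constant of the procedure) and
   round(n_injured_target / ratio) uninjured samples (default ratio 0.136 →
   4,779), without replacement where possible.
3. **SMOTETomek.**  Tomek links — mutual opposite-class nearest neighbours
   under Euclidean distance — lose their majority member only; minority
   counts are never reduced.  SMOTE then grows the minority to the
   configured minority:majority balance (default 1.0) by
   d_new = d + u·(d_n − d), u ~ U[0, 1), d_n one of the smote_k = 5 minority
   nearest neighbours; parent, neighbour and u are recorded for every
   synthetic point, so convexity is auditable.  A literal mode
   (`smote_mode: "literal"`) interpolates with (d − d_n) instead, i.e. away
   from the neighbour; the standard direction is the default because the
   away-from-neighbour form extrapolates outside the minority hull.

## Models

**Auto-encoder.**  Encoder: conv 3×3 (32) → pool 2 → conv 3×3 (64) → pool 2
→ dense → latent 5; decoder mirrors it with nearest-neighbour ×2 upsampling
and a final conv to 10 channels with tanh.  Hidden layers use SELU with
batch normalization (after the affine transform, before the activation) and
dropout 0.1; the latent layer is dense + SELU without dropout so the code is
deterministic at inference.  Loss is mean squared reconstruction error.
All widths are config-exposed; the two-stage 32/64 shape is the package's
default for the 8×8 geometry.

**Classifier.**  Four hidden layers of 50 SELU units (batch-norm + dropout),
one sigmoid output, focal loss with α = 1 − n_minority/n_total computed from
the *original* training-window counts (≈0.986 at reference scale — the class
weight encodes the true imbalance even though training happens on rebalanced
data) and γ = 3.5.  At γ = 0, α = 0.5 the loss is exactly half the binary
cross-entropy (tested to 1e−12).  Probabilities are clamped to
[1e−7, 1 − 1e−7].

**Optimization.**  Adadelta (initial step 1.0, decay ρ = 0.95, ε = 1e−6) for
both models; epochs 100, batch 512 by default.  Both networks, all layers,
and the optimizer are implemented in-package on numpy with reverse-mode
gradients (verified against finite differences in development); training is
deterministic for a fixed seed.  Adadelta's adaptive step needs some tens of
updates to warm up, so very small datasets should use smaller batches (the
test suite does).

**Numerical details.**  Max-pool ties split the gradient equally; batch-norm
uses exponential running statistics (momentum 0.9) at inference; weights are
LeCun-normal initialized (appropriate for SELU).

## Evaluation protocol

Athlete-level hold-out (no athlete on both sides; overlap raises).  Each of
the 5 default repeats: select a fitting subset (default 90%) of the training
windows by a deterministic low-discrepancy index sequence — additive
golden-ratio by default, Sobol optional — with a per-repeat offset, resample
it by the three steps, train both models, validate on the *entire* training
set, test on the held-out athletes.  Metrics: sensitivity, specificity,
Gmean = √(sens·spec) (the identity is asserted on every emitted metric
set), ROC-AUC (rank probability; invariant under strictly monotone
transforms).  Confusion metrics use a default threshold of 0.5,
config-exposed — with α ≈ 0.99 the operating point is sensitivity-heavy, and
deployments should tune it.  Reported metrics are rounded to 3 decimals,
percent differences (100·(a−b)/b, with companion mean difference b−a) to 1.

Welch's ANOVA and the Games-Howell post-hoc test (studentized-range
p-values, Welch–Satterthwaite degrees of freedom) compare metric groups
across repeated runs; both are implemented from the standard formulas on
scipy distributions and cross-checked against pingouin in the test suite.

## Shapley attribution

Contributions are estimated against a background set: a feature is "present"
(from the explained sample) or "absent" (from a background sample).  With
≤ 10 features the exact enumeration over all 2^F coalitions is used, so
additivity (Σφ + base = f(x)) is exact; otherwise permutation sampling.
Surface A explains each of the 5 latents by the 10 input variables, masking
whole image channels — pixel contributions within a channel are therefore
summed by construction, landing attribution on the named variables.
Surface B explains the classifier output by the 5 latents.  Importance is
the mean *absolute* per-sample contribution (a signed-mean literal mode
exists); relative importance normalizes to sum to 1.

To identify which latent carries the volume signal, use the **raw** mean
|SHAP| of the volume channels (total km + alternative hours), not the
row-normalized share: normalizing per latent divides by that latent's total
activity and so penalizes latents that encode more of everything, flipping
near-ties that the classifier's usage (which scales with raw latent
variation) does not.

## Synthetic data: what it emulates, what it does not

The generator draws per-athlete profiles (base loads, day-to-day spread,
rest-day probability, a lognormal frailty with σ = 0.25) and daily loads
with a slow autoregressive drift creating heavy- and light-load blocks.
Injury on the day after day t is Bernoulli with logit
c + β_vol·z(7-day cumulative volume) + β_jump·z(acute day-over-day jump) +
log frailty, where volume = total km + alternative hours and the z-scores
are **within-athlete** standardizations: per-athlete min-max normalization
(the method's own preprocessing) erases absolute scale, so a signal the
pipeline could in principle recover must live in relative load — consistent
with acute:chronic workload reasoning.  The intercept c is calibrated by
bisection to the target prevalence (default 1.3%); the calibration check
allows 30% relative deviation plus three binomial standard deviations, so
small cohorts do not fail on sampling noise alone.  Defaults β = (1.0, 1.5)
were chosen once so that the generator's own latent predictor separates
injured from uninjured windows with AUC ≈ 0.9 — strong enough that a lossy
pipeline retains a detectable signal, far stronger than real training logs.

Not emulated: injury spells lasting several days, missing or irregular
logging, seasonality, inter-variable causal structure beyond exertion
tracking the day's kilometres, and any absolute-load risk component.
Passing tests therefore show that the pipeline recovers a relative-load
signal planted under its own assumptions; they say nothing about effect
sizes in real cohorts, where discrimination is far weaker.

## Problem sizes used by the tests and the acceptance script

The end-to-end experiments run at 30 athletes × 200 days (~5,800 windows,
~75 injuries), resampling scaled to 300 injured at ratio 0.136, auto-encoder
16/32 channels × 30 epochs, classifier 60 epochs — sizes chosen so a full
planted-vs-null comparison runs in minutes on one CPU while leaving the
protocol intact.  The resampling-count checks run at the reference scale (64
athletes × 400 days) with the stock 650 / 0.136 plan.  The acceptance script
averages test AUC over three repeats, each with a fresh athlete split:
with only six test athletes and ~10–20 test-set injuries, a single split's
measurable AUC moves by ±0.1 from split sampling alone (the generator's own
oracle predictor shows the same spread), so the split-averaged mean is the
meaningful estimate of generalization.

## Known limitations

* The 5-dimensional unsupervised bottleneck discards class-relevant
  information: a linear probe on the latents tracks the deep classifier
  closely, and both sit below the generator's oracle AUC by an amount that
  varies with the training realization.  Representation learning, not
  classifier capacity, is the binding constraint.
* The attribution rank check (volume latent first) is a qualitative
  diagnostic; when the pipeline only marginally recovers the signal, latent
  roles mix and the rank becomes unstable.
* Exact Shapley enumeration is exponential in features; it is feasible here
  only because both surfaces have ≤ 10 features.
* The adadelta implementation follows the standard accumulator form; other
  conforming implementations may reach slightly different optima, so
  cross-backend loss histories are comparable only qualitatively.
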