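# Methods

## Problem and data model

A windowing record is one event from clinical practice: operator *i* set
window level/width (WL, WW) on series *n* of imaging condition *j*, where a
condition is an acquisition-sequence × body-region pair (e.g. brain
T1WI-SE). Windows are equivalently expressed as limits, UW = WL + WW/2 and
LW = WL − WW/2, and back (WW = UW − LW, WL = LW + WW/2); the package applies
these identities in both the native and the standardized frame. Records and
images are split into training and test sets at the *patient* level
(default 7:3), so no patient contributes to both.

## Intensity and window standardization

Native MR intensities carry arbitrary scanner units, so raw windows are not
comparable across images. Standardization follows the histogram-landmark
scheme:

- **IOI.** Only voxels with intensity strictly greater than zero enter the
  histogram (zero and negative values are background or padding).
- **Landmarks.** The IOI's 1st, 10th, ..., 90th and 99th percentiles, using
  linear interpolation between order statistics (NumPy's default, the
  "type 7" convention). The convention is shared by the implementation and
  its test oracles; the choice shifts landmarks only marginally.
- **Scale training.** Per condition, each training image's landmark vector
  is affinely rescaled so its 1st-percentile value maps to 1 and its
  99th-percentile value to 100, and the rescaled vectors are averaged
  element-wise. The first and last node are therefore exactly 1 and 100.
  Images with zero landmark span (1st = 99th percentile) carry no usable
  histogram and are excluded with a warning. Scales are trained on the
  training split only.
- **Mapping function.** An image's landmarks (source knots) against its
  condition's scale nodes (target knots) define a piecewise-linear map,
  interpolating between knots and extending the terminal segments' slopes
  indefinitely beyond them. Slope extension (rather than clamping) keeps
  the map a bijection of the real line, which matters because clinical
  window limits routinely exceed the 99th-percentile landmark and may fall
  below zero. Coincident source knots — common on quantized or
  low-dynamic-range images — are merged into one knot paired with the mean
  of their target nodes (and symmetrically for any resulting target ties);
  fewer than two distinct knots raises an unmappable-image error.
- **Window standardization** applies the forward map to LW and UW
  independently and reassembles (sWL, sWW); destandardization applies the
  exact piecewise-linear inverse. Monotonicity guarantees sWW > 0.

## The statistical model

Standardized pairs Yₙ = (sWLₙ, sWWₙ) follow

    Yₙ ~ BivariateNormal(μ_{iₙ jₙ}, Σ_{iₙ})
    μ_{ijk} = β₀ₖ + β₁ₖ x₁(i) + ... + γ_{ijk},      k ∈ {1, 2}

with dummy coding x_c(i) = 1{i = c+1} (operator 1 is the reference), an
operator-specific covariance Σᵢ, and a random effect γ_{ijk} ~ N(0, τ_j²)
whose spread is condition-specific and shared across operators and
components, exactly as indexed. A `condition_only_gamma` flag collapses γ
to a condition-only effect shared by operators, as a sensitivity variant.

Priors are weakly informative, standing in for flat priors while keeping
the posterior proper: βₖ ~ N(0, 100²) per entry; τ_j ~ Half-Cauchy(25); Σᵢ
decomposed into component scales s₁, s₂ ~ Half-Cauchy(25) and a correlation
uniform on (−1, 1). All scales are in standardized units, where typical
windows span 1–100, so these priors are effectively flat over the
plausible range. `ModelSpec.fixed_tau` / `fixed_sigma` pin those parameters
(point priors), which makes the remaining posterior exactly Gaussian — the
validation tests exploit this to compare the sampler against a closed-form
linear-Gaussian oracle.

## Posterior computation

Sampling uses a blocked Gibbs sampler:

- **γ cells** and **β** have exact multivariate-normal full conditionals
  (conjugate normal-normal updates, batched over the I×J grid with explicit
  2×2 linear algebra).
- **Recentering moves.** The directions "β₀ₖ up, all γ··ₖ down" (and each
  operator-dummy coefficient against its own γ row) leave every μ — and
  hence the likelihood — unchanged, so plain Gibbs random-walks along them
  arbitrarily slowly. After each sweep the sampler draws these translation
  coordinates from their exact Gaussian conditionals (determined by the β
  and γ priors alone), which removes the slow mode; without this step
  split-Rhat on β and γ stalls above 1.1 at desk scale.
- **Σᵢ** is updated by an independence Metropolis step: a joint proposal
  from the likelihood-shaped inverse-Wishart IW(nᵢ + 2, Tᵢ + 0.1·I₂) (Tᵢ =
  residual scatter), accepted against the half-Cauchy/uniform prior mapped
  to the matrix measure. Coordinate-wise updates of (s₁, s₂, r) were
  rejected: they mix arbitrarily slowly when the posterior correlation
  approaches ±1. Acceptance is high because the prior is nearly flat where
  the likelihood has mass. The 2×2 inverse-Wishart density and Bartlett
  sampler are implemented in closed form (unit-tested against scipy).
- **τ_j** is updated by univariate slice sampling on log τ (stepping-out
  plus shrinkage), with the Half-Cauchy prior and Jacobian included.

Numerical guards: component scales and τ are floored at 1e-8 so that
degenerate data (zero residual variance) cannot overflow the precision
matrices; batched 2×2 Cholesky clamps at 1e-300.

Sampler profiles: the default is 4 chains × (1000 warmup + 2500 retained
draws), unthinned — desk-scale problem sizes (tens of cells, hundreds of
records) converge comfortably within it. A `reference()` profile (4 chains,
50 000 iterations per chain of which 1000 warmup, post-warmup draws thinned
by 5) reproduces a heavier budget; the interpretation of "iterations" as
total-per-chain-including-warmup is a documented reading, not a fact of the
source protocol. Chains are seeded from a single SeedSequence, so runs are
bit-reproducible given (seed, settings).

Convergence is judged by split-Rhat (each chain halved; computed via arviz
`method="split"`, cross-checked against the textbook formula in tests) for
every scalar parameter, with verdict "converged" iff all values are below
1.1. Split-Rhat is stricter than the original between/within statistic and
also detects within-chain drift. Parameters pinned by point priors are
excluded (Rhat is undefined at zero variance). The posterior means μ̂_{ijk}
over retained draws form the soWL/soWW table; cells with non-positive mean
soWW are flagged with a warning rather than silently used.

Empty (i, j) cells are allowed and warned about: their γ draw is
prior-driven, which is precisely the mechanism by which the model produces
a window for a condition an operator never adjusted.

## Prediction

For a series, operator and fitted model: resolve the condition (an
explicit, user-authored fallback map may substitute a modeled condition for
an unknown one — substitution is opt-in and logged, never inferred
automatically); build the image's own mapping from its landmarks and the
condition scale; convert (soWL, soWW) → (soLW, soUW); apply the inverse
map; convert (oLW, oUW) → (oWL, oWW). Every intermediate is retained on the
Prediction object for audit. A predicted native width below 1 intensity
unit is clamped to 1 with a warning (display hardware needs positive
width); the clamp can only trigger on images whose landmark span is orders
of magnitude narrower than the standard scale.

## Evaluation

MRE = mean |(ŷ−y)/y| × 100, MAE = mean |ŷ−y|, and Pearson's ρ with
population (1/T) normalization in both covariance and standard deviations
(the choice cancels in ρ but is fixed for documentation). MRE requires
nonzero truth; ρ requires non-constant inputs — violations raise errors
naming the offending index rather than returning NaN. Metrics are computed
separately for WL and WW, stratified by operator, and the "Average" row is
the unweighted mean of the operator-level metrics (the pooled-record
alternative is logged at debug level). The naive baseline predicts each
condition's training-set mean WL/WW pooled over operators; a per-operator
variant is available behind a flag for sensitivity analysis.

## Synthetic studies

`SimulationScenario` specifies: per-condition intensity recipes (log-normal
mixtures, ≥1000 voxels per image), a per-image uniform gain/offset
injecting scanner-unit variation (the offset can push voxels to or below
zero, exercising the IOI filter), operator count, true β, τ, Σ in
standardized units, patient count and series per patient, and the split
fraction. Windowing behavior is generated from the model itself: draw
γ ~ N(0, τ_j²), draw standardized pairs from the bivariate normal
(rejecting and redrawing sWW ≤ 0; a rejection rate above 10% warns that the
scenario's noise is too large for its mean), then destandardize through
each image's own mapping using pilot scales trained on the training split —
the same protocol the pipeline applies, so re-standardizing the native
records reproduces the generator's draws to mapping tolerance.

The default scenario: 3 operators, 4 conditions with distinct mixture
shapes, 60 patients × 2 series (120 images, 360 records), operator effects
of 5–12 standardized units against within-operator noise of 2–4.5 units and
τ between 2.5 and 4 — heterogeneity large enough to be clinically visible
but not dominant, chosen once as a realistic regime for three colleagues
windowing the same scanner's output. The `homogeneous()` control removes
both operator effects and gain/offset variation; with no signal of either
kind the framework's advantage over the naive mean vanishes, as it should.

What the generator does *not* emulate: anatomical structure (histograms
only, no spatial content), scanner/site effects beyond a global affine,
per-slice windowing, operator drift over time, and heavy-tailed or
multimodal operator behavior. Passing tests therefore demonstrate that the
pipeline recovers the model's structure when the model is true and that
every deterministic transformation is exact — not that clinical data meet
these assumptions.

## Problem sizes and defaults

Tests and the acceptance script run the default scenario (360 records, 12
cells) and model-recovery instances up to 3 operators × 5 conditions × 200
records/cell; a full pipeline run takes ~15 s single-threaded at the
default sampler profile. These sizes were chosen as comfortable desk-scale
study conditions; the machinery itself is O(N) in records per sweep and has
no intrinsic size limits.

## Known limitations

- The Gibbs sampler is specific to this model (bivariate outcome, dummy
  coding, one random-effect grid); adding covariates (e.g. scanner or
  facility effects) requires new conditionals.
- Σ is operator-specific but condition-constant; heteroscedasticity across
  conditions is absorbed by standardization or not at all.
- Windows are assumed recorded per series, not per slice.
- The truncation mismatch (the generator rejects sWW ≤ 0; the model
  assumes an untruncated bivariate normal) is negligible at the default
  scenario where the mean width sits ~20 standard deviations above zero,
  but would bias fits in scenarios with widths near zero.
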