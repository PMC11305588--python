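# Methods

## Model

Density follows dp/dt = r p − S p²/K with per-capita fitness
f = r − S p/K, and the active regime's capacity is
K_i(t) = A_i − B_i p(t − d) + C + Δ(t).  The sign convention is applied
literally: a *positive* B degrades capacity as (delayed) density rises; a
negative B is a positive feedback.  The equilibrium of a rung,
p* = r(A + C)/(S + rB), exists and is positive when S + rB > 0 and
A + C > 0; `equilibrium_density` refuses the other cases.

The switch rule is evaluated once per step from the instantaneous
fitness under the current regime.  In `literal` mode it is memoryless:
f_min < f (strict) steps one rung down (bounded at the first),
f ≤ f_min steps one rung up (bounded at the last — ladder exhaustion is
the innovation ceiling, never an error).  With a two-rung ladder this
reduces exactly to "if f_min < f use K₁, else K₂"; near the threshold it
chatters between adjacent rungs, which is the intended behaviour for the
noise-triggered-innovation experiments.  `ratchet` mode applies the same
rule but never returns below the highest rung reached, modelling
innovations that persist once adopted; the ladder and
overshoot presets use it so a single committed transition is visible.
The strict inequality matters: with f_min = 0 under deterministic
climate, fitness approaches zero from above and no switch ever fires —
the population is Malthusian-trapped, and only climate noise (or a
positive f_min) can trigger innovation.

### Numerical scheme

Fixed-step explicit Euler, default dt = 0.01 generations.  The delayed
density p(t − d) is read from the solution history by linear
interpolation; history before t = 0 is the constant p0.  Δ(t) is drawn
i.i.d. once per whole generation (Gaussian with sd `delta_amplitude`;
a variance-matched uniform option exists) and held constant within the
generation, so a run is bit-reproducible from (parameters, seed).  The
dynamics here are smooth and slow; step-halving changes terminal
densities by < 1e−3 on every preset (tested, not assumed), and against
the closed-form logistic (d = 0, B = 0) the maximum absolute error at
dt = 0.01 is ~4e−4.  Capacity reaching ≤ 0 aborts with a diagnostic by
default; an explicit `capacity_floor` clamps instead, because silent
clamping hides parameter pathologies.  Non-finite states abort with the
step index.

### Preset choices

* Time unit: one generation = 30 calendar years.
* `set1_climate_ladder`: S = 1, no innovations, f_min = 0, and a
  stepwise C(t) doubling every 1000/30 ≈ 33.3 generations (1 → 2 → 4
  over three millennia): expansion driven by climate alone.
* `set1_innovation_ladder`: S = 1, C = 1, four rungs with A = 0, 1, 3, 7
  so each adoption doubles total capacity (K = 1, 2, 4, 8), f_min = 0.1,
  ratchet mode.  The doubling spacing keeps successive switches ~5
  generations apart so all three transitions resolve at 1-generation
  bins.
* `set2_A_sweep` / `set2_C_sweep`: r = 0.25, S = 0.5, d = 25, two rungs
  with B₂ = +0.3 under the literal sign convention (density degrades
  capacity), A ∈ {0.5, 1, 2, 3} at C = 1, or C ∈ {1, 2, 3} at A = 0.5;
  f_min = 0.1, ratchet mode.  The degrading sign is the one that
  produces the delay-driven overshoot and recession these experiments
  are about: with the feedback sign flipped the linearized system has a
  real stable root and the approach is monotone (that regime is covered
  by tests, not presets).
* `set3_stochastic`: as the A = 0.5 sweep but f_min = 0 and
  Δ ~ N(0, 0.01), C ∈ {1, 3}, literal mode: climate variability, not
  pressure detection, triggers the innovation.
* p0 = 0.01 throughout ("a population entering a region near zero").

A useful scaling fact about the sweeps: after the switch the fitness
dynamics depend only on p/p*, so the *duration* of the recession (time
with f < 0, set by the delay and the damping rate
c = S B (r/(S + rB))²) is invariant to A and C; what grows along the
sweeps is the overshoot's magnitude (and the length of the demographic
transition grows with A, since the adopted rung sits further from the
switch density).  `recession_summary` therefore reports overshoot
(max p − p* of the terminal regime, floored at 0) and total time with
f < 0; on a finite horizon the latter includes the symmetric dithering
of the damped tail and should be compared across runs of equal horizon
only.

## Phase-plane diagnostics

Per-capita growth of a binned series is ln(v_{t+1}/v_t), one element
fewer than the input; bins with zero density make the adjacent growth
elements NaN (flagged with a warning, never imputed).  The phase path
pairs growth_t with density_t, oldest first, excluding undefined pairs.
All detectors are invariant to uniform rescaling of density, since
empirical mean-KDE curves are in arbitrary units.

*Transitions.*  After a centered moving average (window 3 bins), local
maxima of growth are found with prominence ≥ `rise_threshold`
(default 0.005 per bin); event bounds are the growth minima between
consecutive peaks, and an event qualifies if growth rises and falls by
at least the threshold and density gains ≥ `min_density_gain`
(default 10%) start to end.  Events partition the axis, so they are
disjoint and chronological.  The defaults were set so the simulator
presets reproduce their constructed counts (three ladder transitions; a
single transition at a two-epoch capacity jump; none on a monotone
logistic); they are exposed and recorded in the CLI's output metadata.

*Cycles.*  The signed rotation of the path about a centroid (global
mean by default, window-local with `window`) is accumulated; each full
2π emits a cycle event whose center is the mean density over the loop
span.  Axes are rescaled to unit range first (the winding count of a
closed loop is unaffected).  On exactly closed constructions the count
equals the analytic winding number (a 1e−9 slack absorbs float
round-off).  Known bias: a decaying spiral winds fewer turns about a
fixed centroid than its period count once its radius shrinks below the
centroid offset, so cycle counts on strongly damped paths are
conservative.

*Logistic trend.*  v(t) = K/(1 + exp(−ρ(t − t₀))) by least squares
(scipy `curve_fit`, initialized from a logit-linear regression).
Constant input returns a flagged degenerate fit; non-convergence is
reported, never silently returned.

## Mean-KDE demography

Dated samples (site, calendar age in cal BP, 1σ error) stand in for
calibrated radiocarbon dates: calibration itself is out of scope, so a
"calibrated sample" is modeled as Normal(age, σ).  `mean_kde` accepts an
`age_sampler` hook for arbitrary per-sample age distributions should
calibrated densities become available.

Procedure per iteration: dates are grouped by site and single-linkage
clustered on age with cut height h = 100 yr (scipy); one member per
cluster is drawn uniformly, perturbed by its σ, and a fixed-bandwidth
(50 yr) Gaussian KDE is evaluated on a 1-year grid over 4000–200 cal BP,
normalized to integrate to 1 over that grid.  The 200 iteration KDEs are
averaged, summed into 30-year bins (oldest bin edge at 4000), and
trimmed to 3700–300 cal BP against edge effects; the envelope is the
2.5/97.5 percentile of the per-iteration binned KDEs.  Clusters are put
in a canonical order (by age within and across clusters) so the
bootstrap is invariant to input sample order.  Axis convention is cal BP
(larger = older); `MeanKDE.to_forward_series()` re-indexes to forward
time before the phase-plane diagnostics.

The synthetic date generator draws ages by inverse-CDF sampling of an
occupation curve and assigns sites by preferential attachment (a new
date joins a site with probability proportional to 1 + its current
count), so a few sites end up heavily oversampled — the situation the
within-site clustering exists to neutralize.  Defaults: 50 sites per
1000 dates (the scale of a regional radiocarbon database; far fewer
sites makes single-linkage chain entire sites into one cluster and
starves the per-iteration KDE), age errors uniform in 20–60 yr.  What
the generator does not emulate: calibration-curve plateaus and wiggles,
taphonomic loss, and spatially structured sampling; recovery results on
it therefore speak to the estimator's statistical behaviour, not to
calibration-induced artifacts.

## Counterfactual intervention analysis

A structural time-series analogue of Bayesian causal-impact analysis,
deliberately minimal: the response over the pre-intervention window is
modeled (statsmodels `UnobservedComponents`) as a local level plus a
static regression on the covariate, the covariate standardized on the
pre-window only (no leakage).  The fitted model is projected over the
post window given the observed covariate there, and ≥ 1000 joint sample
paths simulated from the fitted state space provide the predictive
uncertainty.  Pointwise effect: observed − counterfactual mean per bin.
Relative effect: 100 × (Σobs − Σcf)/Σcf over the post window, interval
by applying the same functional to each draw, and the tail probability
is the fraction of draws whose implied effect crosses zero against the
sign of the point estimate.  Parameters are estimated by maximum
likelihood rather than full Bayes, so intervals are approximate
("inspired by, not parity with" the spike-and-slab machinery); on the
synthetic lift scenarios the null 95% interval covers 0% in ≈95% of
replicates and an injected +50% lift is covered in ≥90% (tested).
Pre-windows must span ≥ 10 bins; degenerate (zero-variance) covariates
are refused.

## Problem sizes

Default test and acceptance runs use: horizons of 100–400 generations at
dt = 0.01; 1000 synthetic dates / 200 KDE iterations for the recovery
study; 200 null and 100 lifted replicates (1000 predictive draws each)
for counterfactual calibration.  These sizes give stable results for
the properties checked — orderings, counts, rank correlations, coverage
proportions — which are insensitive to further scaling.

## Known limitations

Single population, no spatial coupling or age structure; explicit Euler
only (adequate for these smooth dynamics, not for stiff variants); the
transition/cycle detectors are heuristics calibrated on the simulator's
own constructions, and their thresholds should be revisited for noisy
empirical series; no radiocarbon calibration or reservoir correction;
counterfactual analysis supports a single covariate and makes no formal
identification claims.
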