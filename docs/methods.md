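# Methods

## Process models

Three nested process models describe sustained (aerobic) travel speed
`v` (m/s) as a function of body mass `M` (kg). All three share a common
core: metabolic power input scales as `M^a`, maximum locomotion efficiency
as `M^b`, so *potential* travel speed — the speed permitted by energy
supply and locomotion efficiency alone — scales as `v0 * M^c` with
`c = a + b`. They differ in how much of the travel time budget must be
diverted to dissipating metabolically produced heat:

- **metabolic**: no heat-dissipation time; `v = v0 * M^c` (power law).
- **constant_hd**: heat-dissipation time per unit distance is a
  mass-independent constant `k0` (s/m);
  `v = (1/k0) * M^c / (M^c + 1/(v0*k0))`, a saturating curve with ceiling
  `1/k0`.
- **allometric_hd**: heat-dissipation time per unit distance grows with
  mass as `k_lambda * M^d` (larger animals have more thermal inertia);
  `v = (1/k_lambda) * M^c / (M^(c+d) + 1/(v0*k_lambda))`, a hump-shaped
  curve with interior maximum at `M* = (c*K/d)^(1/(c+d))`,
  `K = 1/(v0*k_lambda)`.

`v0` (m s⁻¹ kg⁻ᶜ) is mode-specific (flying, running, swimming) and never
pooled; `c`, `d`, and the heat-dissipation constants are shared across
modes by default, with optional per-mode `c` and per-realm
(aquatic/terrestrial) `k` variants selected through `ModelSpec`.

The mechanistic intermediates behind these forms (power normalisations,
time budgets, heat balance) are algebraically eliminated into `v0`, `k0`,
`k_lambda` and are not represented at runtime. The theoretical expectation
for the rise exponent is additive, `c = a + b`: `exponent_bounds((0.80,
0.97), -0.67)` → `(0.13, 0.30)` for the customary ranges of the aerobic
metabolic exponent and the locomotion-efficiency exponent.

Nesting conventions: `d = 0` is a valid `allometric_hd` parameterisation
and reproduces `constant_hd` with `k0 = k_lambda` exactly (so the nesting
is testable); `peak_mass` refuses `d = 0` explicitly because the curve
then has no interior maximum. `k0 -> 0` recovers the metabolic model in
the limit.

### Numerical evaluation

All curves are evaluated in natural-log space,
`ln v = -ln k + c ln M - logaddexp((c+d) ln M, -ln(v0 k))`,
so `M^(c+d)` never materialises on the natural scale. The supported mass
range in tests spans 10⁻¹² – 10¹² kg and beyond without overflow; the
empirical range of interest is 2×10⁻¹⁰ – 1.4×10⁵ kg.

## Data model and priors

Observations are species-level records `(species, mass kg, speed m/s,
mode, realm)`. The likelihood is Gaussian on base-10 log speed:

    log10(v_i) ~ Normal( log10 v(M_i; theta), sigma )

so `sigma` is in log10(m/s) units. Prior families: half-normal on the
exponents `c` and `d`, gamma on `v0` and the `k` constants, half-Cauchy on
`sigma`. Default hyperparameters (all overridable via `PriorConfig`):

| parameter | prior | default | rationale |
|---|---|---|---|
| c, d | half-normal(s) | s = 1 | exponents are O(0.1–1) |
| v0 | gamma(shape, rate) | (1, 0.01) | diffuse over ~0.01–300 m s⁻¹ kg⁻ᶜ, covering flying (~30) to running (~0.3) |
| k0, k_lambda | gamma(shape, rate) | (1, 1) | diffuse over plausible s/m scales |
| sigma | half-Cauchy(s) | s = 2.5 | weakly informative scale prior |

The acceptance script refits the default synthetic dataset with all prior
scales broadened 10× and reports the posterior mean of `c` under both, as
a prior-sensitivity check.

## Sampling

Positive parameters are sampled on the natural-log scale (Jacobians folded
into the prior) because they span orders of magnitude. Sampling uses an
affine-invariant ensemble MCMC (emcee) with a move mixture of
differential-evolution (0.6), DE-snooker (0.2), and stretch (0.2) moves;
the stretch component speeds up scale expansion when the posterior is
prior-dominated.

The ensemble is initialised around a posterior mode found by multi-start
Nelder-Mead (one data-driven start plus starts drawn from the priors), in
a Gaussian ball whose per-dimension scale is the Laplace
(inverse-curvature) scale clipped to [1e-6, 2]. Mode-anchored
initialisation was chosen over fully prior-dispersed walkers because
stragglers from a diffuse initialisation do not reliably merge within the
adaptation budget; the clip ceiling of 2 keeps the initial ensemble
dispersed on the prior's own log-scale when the data are weak.

`McmcConfig` defaults to 3 chains × (1,500 adaptation + 3,000 sampling)
iterations, retaining 3 × 3,000 = 9,000 draws. For the ensemble sampler
this maps to: `warmup_iterations` ensemble moves discarded, then 3×
`sampling_iterations` internal moves thinned back to the retained-draw
target across walkers (the number of walkers is `max(2*ndim+2, 18)`,
rounded even). The 3× internal oversampling lowers the autocorrelation of
retained draws so that the diagnostics below are met with margin at the
default problem size.

Walkers are treated as chains for diagnostics: rank-normalised split-R̂
and bulk ESS (via ArviZ) are computed for every parameter, with thresholds
r̂ ≤ 1.01 and ESS > 1,000. Misses emit a `ConvergenceWarning` and are
recorded on the result object; they are never silently dropped. Fits are
deterministic given `McmcConfig.seed`.

## Model comparison

`psis_loo` estimates the expected log pointwise predictive density (ELPD)
by Pareto-smoothed importance sampling from the (chain, draw, observation)
log-likelihood array, reported also as LOOIC = −2·ELPD; observations with
Pareto k > 0.7 are flagged, and `exact_loo` (brute-force n refits) is both
the validation oracle and the fallback for flagged observations. `compare`
ranks models fitted to the identical dataset; the SE of each ΔELPD is
computed from the paired pointwise ELPD differences,
`sqrt(n * var(elpd_i_best − elpd_i_rival))`, and reported on the deviance
scale (×2) next to ΔLOOIC. The best model is *preferred* only when every
rival's ΔLOOIC exceeds 2× its SE; rivals within 2×SE are
*indistinguishable*.

## Prediction

For a mass grid (default: 200 log-spaced points spanning the observed
range per mode, extended one decade each side), `predict_curve` reports:

- the posterior mean of the expected curve `v(M; theta)` over draws;
- the central 90% **credible interval** of the expected curve (quantiles
  of `v(M; theta)` across draws);
- the central 90% **prediction interval** for a new observation: the
  quantile of the equal-weight Gaussian mixture
  `Normal(log10 v(M; theta_s), sigma_s)` over draws `s`, solved by
  bisection in log10 space — deterministic given the draws, no simulated
  noise. The PI encloses the CI by construction.

Grid points outside the observed mass range of the mode are flagged
(`in_observed_range = False`) so plots can dash the extrapolated segments.
`predictive_cdf` evaluates the same mixture CDF at observed speeds, which
gives prediction-interval coverage directly (inside the central 90% PI ⇔
CDF value in (0.05, 0.95)).

## Synthetic data

`generate_dataset` is the data model run forward: per mode, log10 masses
are uniform over a configurable interval, expected log10 speeds come from
the chosen process model, and Gaussian noise with sd `sigma` is added.
`default_empirical_emulation` emulates the structure of the empirical
compilation the models were built for: 699 records split evenly across
modes (233 each), per-mode log10(kg) mass ranges flying [−10, 1.2],
running [−9, 4], swimming [−6, 5.15] (a plausible partition whose union
spans the published extremes 2×10⁻¹⁰ and 1.4×10⁵ kg), truth =
`reference_parameters()` (the published posterior means v₀ = 30.54 / 0.28
/ 0.39, k_λ = 0.033, c = 0.27, d = 0.24), and residual scatter σ = 0.3 —
the source analysis does not publish its residual sd, so 0.3 is this
package's documented, overridable choice, giving scatter comparable to
published speed-mass compilations. Realms default from mode (swimming →
aquatic, else terrestrial).

What the generator deliberately does **not** emulate: the taxonomic
composition, study-level clustering, measurement-method heterogeneity,
non-uniform mass distributions, or mass-measurement error of real
compilations. Passing recovery and calibration tests on this generator
therefore demonstrates the correctness and calibration of the machinery
under the model's own assumptions, not robustness to real-data
pathologies.

## Problem sizes used by the test and acceptance suites

Recovery and model-selection experiments run at the emulated size
(n = 699) with the full MCMC protocol; interval calibration uses 2,000
held-out observations; the PSIS-vs-exact-LOO cross-check runs at n = 20
with 2,000-draw fits (21 refits); simulation-based calibration uses 16
replicates of single-mode n = 30 datasets with shortened chains. These
sizes are the package's choices for a thorough desk-scale validation.

## Known limitations

- The ensemble sampler's diagnostics are computed across walkers, which
  are not fully independent chains; the rank-normalised split-R̂ still
  detects non-stationarity within walker histories, and the mode-anchored
  initialisation means R̂ is less sensitive to multimodality than with
  overdispersed starts. No multimodality has been observed for these
  likelihoods.
- `sigma = 0` is accepted in a `ParameterSet` for noise-free generation,
  but the Gaussian likelihood is degenerate there; fitting requires
  strictly positive noise (the near-noise-free tests use sd 10⁻⁶).
- Per-realm `k` variants assign realm by locomotion mode when a dataset
  does not state one; records crossing that convention (e.g., swimming
  mammals hauled out) need explicit realm values.
- No hierarchical partial pooling, phylogenetic covariance, or
  temperature dependence: pooling is all-or-none per parameter, matching
  the model variants the package is designed to compare.
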