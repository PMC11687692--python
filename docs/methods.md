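# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `floeseal`.

## The occupancy model

Seal counts per ice floe are modelled as NB2 negative binomial,
Var(y) = μ + μ²/θ, with a log link. The linear predictor is piecewise linear
in floe area with two breakpoints, encoded in the hinge basis
h(a, ψ) = max(0, a − ψ):

log μ = β₀ + β₁a + δ₁h(a, ψ₁) + δ₂h(a, ψ₂) + β_r·rough₁₀₀₀ + β_s·sic₇₅₀ + β_d·colony_dist

The hinge coefficients δₖ are slope **increments**, so log μ is continuous in
area by construction and per-segment slopes are cumulative sums
(β₁, β₁+δ₁, β₁+δ₁+δ₂). The reference parameterisation
(`SegmentedModelSpec.default()`) is

| parameter | value | units |
|---|---|---|
| β₀ (intercept) | −7.53 | log scale |
| β₁ (area slope, segment 1) | 0.139 | per m² |
| δ₁ (increment at ψ₁) | −0.136 | per m² (segment-2 slope 0.003) |
| δ₂ (increment at ψ₂) | −0.003 | per m² (segment-3 slope ≈ 0) |
| ψ₁, ψ₂ | 49.84, 481.32 | m² |
| β_r (roughness, 1000 m) | 0.042 | per m |
| β_s (SIC, 750 m) | −0.72 | per unit fraction |
| β_d (colony distance) | 6.19 × 10⁻⁷ | per m |
| θ (NB2 dispersion) | 0.5 | — |

Two of these entries are package decisions rather than externally fixed
values. Published summaries of this model report the post-second-breakpoint
area coefficient with mutually inconsistent estimate/SE/t entries; we resolve
the inconsistency by reading the printed 0.003 as the *derived segment-2
slope* (= β₁+δ₁) and setting δ₂ = −0.003 so that the response plateaus on the
largest floes, which matches the qualitative description of the fitted curve.
The dispersion θ is not reported anywhere; θ = 0.5 is a package default
chosen to produce the strong overdispersion seen in haul-out group sizes
(mostly-zero counts with occasional groups in the tens). Both choices are
configurable.

Colony distance enters in metres; at 10⁴–10⁶ m from a colony the term
contributes 0.01–0.6 to the log mean, consistent with the tiny coefficient.

## Breakpoint estimation

`SegmentedNegativeBinomial.fit()` estimates (β, δ, θ, ψ) by iterative
linearization. At the current ψ the design gains, per breakpoint, the hinge
column h(a, ψₖ) and the indicator column Vₖ = −1{a > ψₖ}; the NB2 fit's ratio
γ̂ₖ/δ̂ₖ is the first-order correction to ψₖ. Iterations use:

- **Profile-likelihood step-halving.** A proposed ψ step is accepted only if
  the hinge-only (profile) log-likelihood does not decrease; otherwise the
  step is halved (up to 6 times). Accepted iterations are therefore
  likelihood-ascending.
- **Stopping.** Convergence is declared when the largest |Δψ| falls below
  10⁻⁶ of the area range, or when two consecutive accepted steps improve the
  profile log-likelihood by less than 10⁻⁷ relative (the ψ wiggle is then
  below likelihood resolution); at most 50 outer iterations.
- **Constraint.** ψ estimates are confined to the [1st, 99th] percentile
  band of the observed areas. The band exists only to prevent boundary
  degeneracy (a breakpoint escaping into the extreme tail where hinge columns
  become collinear); it is deliberately wide because the second breakpoint of
  the reference model sits near the 97th percentile of a realistic right-
  skewed floe-size distribution, and a tighter clamp would exclude it a
  priori.
- **Multi-start.** By default 5 quantile starts for one breakpoint and a 3×3
  quantile grid for two; the best converged log-likelihood wins. The
  `experiments` module uses a single deterministic start at the (0.5, 0.9)
  area quantiles, which on recovery simulations reaches the same optimum at a
  third of the cost.
- **Standard errors.** ψ SEs come from the delta method on γ/δ at the
  solution (Var(γ̂)/δ̂² with γ̂ ≈ 0). Coefficient and θ SEs come from the
  observed information of the joint (β, log θ) likelihood, computed by finite
  differences.
- **Degenerate cases.** Collapsing breakpoints (|ψ₁−ψ₂| below 10⁻³ of the
  range) raise an error suggesting fewer breakpoints; a vanishing hinge
  coefficient (unidentified breakpoint) aborts the start; if every start
  fails the error carries the per-start trace.

The inner NB2 fits alternate IRLS for β (at fixed dispersion) with a bounded
one-dimensional profile maximisation over log θ, warm-started across Muggeo
iterations; θ is capped at ~10⁶, the operational Poisson limit. p-values for
the segment-difference terms are deliberately not printed: the hinge
increments at estimated breakpoints do not have standard Wald reference
distributions (the Davies problem), and no Davies test is implemented.

## Candidate-distribution comparison

`compare_distributions` fits five families with a mean (location, for the
log-normal) log-linear in area: Poisson, NB2, Gamma, Exponential, Log-normal.
The continuous families put no mass on integers, so they enter through the
interval-censored likelihood P(y − ½ < Y ≤ y + ½), left-clipped at zero.
Evaluating continuous *densities* at shifted counts instead would let a
narrow log-normal concentrate arbitrarily much density at the zero class and
win any AIC comparison on overdispersed count data; interval censoring keeps
all five log-likelihoods genuine probabilities and the AICs commensurable.

## Synthetic scenes and the survey generator

The generator emulates the statistical skeleton of a VHR satellite scene of
pack ice, not its radiometry.

- **Floe sizes**: log-normal on area (default meanlog = ln 10, sdlog = 2.0),
  truncated to [1, 5000] m² — heavily right-skewed, median ~10 m², with a few
  floes in the 10³ m² range; a Pareto option exists. No published per-scene
  floe-size distribution exists, so these are package defaults.
- **Geometry**: non-overlapping circles placed by rejection sampling with a
  coarse occupancy grid (largest first); a convex-polygon option adds
  perimeter irregularity. The ice mask is rasterised at pixel-centre
  resolution, so mask area matches summed floe area to within roughly one
  pixel of quantisation per floe-perimeter length.
- **Bathymetry**: Gaussian random field synthesised spectrally (white noise
  filtered by a Gaussian kernel with correlation length 800 m), rescaled to
  the requested mean (−450 m) and standard deviation (60 m).
- **Colonies**: uniform in a frame up to 800 km around the scene, excluding
  the scene itself.
- **Direct covariate laws** (used by `simulate_survey_table` when no rasters
  are in play): sic₇₅₀ ~ Beta(5, 2) (mean 0.71 — dense pack ice);
  rough₁₀₀₀ ~ log-normal(2.95, 0.4) (mean ≈ 21 m); colony distance ~
  U(20, 800) km; companion covariates (SIC at other radii, slope/TRI) are
  noisy monotone transforms of the primary ones so that selection procedures
  face realistic collinearity.
- **Counts**: NB2 draws from the model above; a linear predictor above 50
  aborts with the offending floe named (that always signals mis-scaled
  covariates).

Determinism: every generator is a pure function of (spec, seed); sub-streams
are derived with `numpy.random.SeedSequence([seed, k])`.

What the generator does **not** emulate: spatial autocorrelation of counts
beyond shared covariates, scene-to-scene heterogeneity (weather, prey, time
of day), seal detection failure (false negatives of the upstream detector),
non-circular floe shape effects on the SIC buffers, or geodesy (scenes are
planar). Passing recovery tests therefore demonstrate the estimator's
correctness under the stated generating process, not robustness to these
real-data features.

## Covariate extraction conventions

- SIC buffers grow from the floe **boundary** (not centroid) and exclude the
  focal floe's own pixels; a large floe would otherwise dominate its own
  covariate. Values are pixel-centre fractions in [0, 1].
- Focal terrain metrics on the 3×3 window: slope = |∇z| by central
  differences; TRI = mean |neighbour − centre|; roughness = max − min.
  Any monotone variant would merely rescale β_r, so one convention is fixed
  package-wide and the generator uses the same one.
- Coordinates are planar scene metres, origin at the raster's top-left, y
  down. All distances are Euclidean.
- The edge filter retains a floe iff its polygon lies wholly inside the
  rectangle inset by the buffer (1000 m default, matching the largest
  covariate radius); SIC at 1000 m therefore never reads outside the raster.
- Stratified sampling uses log-spaced area bins (areas span 4 orders of
  magnitude; linear bins would leave most empty) with uniform
  without-replacement draws within bins, up to the per-bin quota.

## Selection stage

The screening forest is a plain variance-split bagged ensemble (sklearn
trees, `mtry` features per split, min leaf 5) with out-of-bag RMSE / R² /
MAE; "accuracy" (exact-match rate of the rounded prediction) is reported for
completeness but never used for selection, since counts have no natural
classification accuracy. Conditional permutation importance permutes a
predictor within cells of the quantile grid (4 bins per conditioner, reduced
until every occupied cell has ≥ 2 rows) of its correlated companions
(|Spearman ρ| > 0.2) and records the OOB-MSE increase, averaged over
permutation repeats. The conditional correction thus lives entirely in the
importance scheme — a deliberate simplification relative to
conditional-inference forests, which replace the split test itself.

All-subsets AIC ranking refits the segmented model for every subset of the
optional covariates (the segmented area terms are always included);
`refit_breakpoints=False` holds ψ fixed for cheap screening. Candidate
models then go to k-fold (default 5) or leave-one-scene-out CV; the final
model is the lowest mean held-out MAPE, ties broken by RMSE.

## Prediction, intervals, metrics, diagnostics

- Scene totals are sums of per-floe μ̂ (exact conservation).
- Bootstrap intervals: nonparametric case resampling of floes, refit per
  replicate, predictions evaluated on the original floes. CI = percentile
  band of the replicate μ̂; PI = percentile band of one NB2 draw per
  replicate at (μ̂ᵇ, θ̂ᵇ), so the PI combines parameter and sampling noise
  and is supported on the non-negative integers. Replicate failure above 5%
  aborts with diagnostics.
- MAPE is undefined per floe (most observed counts are zero), so it is
  computed on observed-vs-predicted **totals within 20 log-spaced floe-size
  bins** within scene, dropping zero-observation bins; RMSE stays per-floe.
  This is an interpretive choice and is stated wherever MAPE is reported.
- Diagnostics: Pearson residuals (y−μ̂)/√(μ̂+μ̂²/θ̂) are correlated against
  μ̂ (Fisher-z CI); White's test uses the LM form — squared Pearson
  residuals regressed on (1, μ̂, μ̂²), n·R² against χ²(2) — because the
  question posed is variance structure across predicted values, not across
  the full regressor cross-product set.

## Validation experiments and problem sizes

The package validates itself on simulation at these scales (chosen to give
stable Monte-Carlo answers at desk-scale runtimes):

- **Parameter recovery** (`floeseal.experiments.recovery_experiment`, also
  the acceptance script): 25 replicates × 60,000 floes; the test suite runs
  a 4-replicate version. Replicate-mean estimates of ψ₁, ψ₂, β₀, β₁, β_r,
  β_s land within a few percent of the generating values.
- **Oracle equivalence**: on 50 single-breakpoint NB datasets (n = 300,
  areas on a discrete grid) the Muggeo estimate falls within one grid step
  of the brute-force profile-likelihood argmax over distinct-x midpoints.
- **Family selection**: NB2 lowest-AIC in ≥ 95/100 replicates of
  NB-generated data.
- **Bootstrap coverage**: 50 replicates × 500 bootstrap refits of a
  well-specified NB2 GLM (n = 800): mean per-floe CI coverage ≈ 0.95.
  Per-replicate coverage is intrinsically noisy because parameter error is
  shared across floes, so only the replicate mean is meaningful.
- **White's test calibration**: empirical size ≈ 0.05 under a homoscedastic
  null (500 reps, n = 1000); power > 0.8 against SD ∝ μ.
- **CPFI behaviour**: null predictors earn ≈ 0 importance (within MC error
  across replicates); a correlated duplicate's conditional importance falls
  below its marginal importance in ≥ 90% of replicates.

## Known limitations

- The segmented fitter supports at most two breakpoints and one segmented
  covariate.
- No Davies-type test for the *existence* of breakpoints; model choice
  between 0/1/2 breakpoints is by AIC.
- No zero-inflated or spatially correlated count extensions.
- Bootstrap refits in the `predict` CLI hold the breakpoint count fixed and
  restart from the point estimates; at small n with weak second kinks,
  replicate non-convergence is possible and is surfaced, not hidden.
- GeoTIFF support covers planar single-band rasters with
  pixel-scale/tiepoint tags only (no CRS machinery, no compression
  negotiation); GeoJSON is written without a CRS member (planar scene
  coordinates).
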