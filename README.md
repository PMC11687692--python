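# floeseal

Occupancy modelling of Antarctic pack-ice seals hauled out on sea-ice floes.

Pack-ice seals (predominantly crabeater seals along the western Antarctic
Peninsula) rest on free-floating ice floes, where they are visible to
very-high-resolution satellite survey. The number of seals on a floe depends
strongly and *non-linearly* on floe size, together with the fine-scale sea-ice
and seafloor environment. `floeseal` implements the full analysis pipeline
around that observation for researchers working on satellite-based wildlife
census:

- **Synthetic pack-ice scenes** — right-skewed floe-size fields, rasterised
  ice masks, spectrally synthesised bathymetry, penguin-colony locations and
  NB2 seal counts generated from a reference occupancy model (real imagery is
  licence-restricted, so every stage is testable on simulation).
- **Covariate extraction** — sea-ice concentration (SIC) in metric buffers of
  150–1000 m around each floe, 3×3 focal bathymetric slope / terrain
  ruggedness index / roughness averaged in 1000 m circles, distance to the
  nearest colony, plus the 1000 m edge-buffer filter and stratified
  size-bin sampling used to build survey tables.
- **Segmented negative-binomial regression** — the statistical core: an NB2
  GLM (log link, Var = μ + μ²/θ) whose log-mean is piecewise linear in floe
  area with *estimated* breakpoints, fitted by iterative linearization of the
  hinge basis h(a, ψ) = max(0, a − ψ).
- **Model selection** — conditional permutation feature importance on a
  bagged regression forest, exhaustive all-subsets AIC ranking, k-fold and
  leave-one-scene-out cross-validation (binned MAPE / RMSE).
- **Prediction and uncertainty** — per-floe and per-scene expected counts
  with case-resampling bootstrap confidence and prediction intervals, and
  residual diagnostics (Pearson residual correlation, White's test).

## The model

For floe *i* with area *aᵢ* (m²), seafloor roughness *rᵢ* (m, 1000 m circle),
sea-ice concentration *sᵢ* (fraction, 750 m buffer) and colony distance *dᵢ*
(m), seal counts are NB2 with

```
log μᵢ = β₀ + β₁aᵢ + δ₁·h(aᵢ, ψ₁) + δ₂·h(aᵢ, ψ₂) + β_r rᵢ + β_s sᵢ + β_d dᵢ
Var(yᵢ) = μᵢ + μᵢ²/θ
```

where δ₁, δ₂ are slope *increments* at the breakpoints ψ₁ < ψ₂, so log μ is
continuous in area and the per-segment slopes are β₁, β₁+δ₁, β₁+δ₁+δ₂.
Breakpoints are estimated Muggeo-style: augment the design with
Vₖ = −1{a > ψₖ}, fit, update ψₖ ← ψₖ + γ̂ₖ/δ̂ₖ, iterate with step-halving;
SE(ψ̂ₖ) follows from the delta method on the ratio. The reference
parameterisation shipped as `SegmentedModelSpec.default()` has breakpoints
near 50 m² and 481 m²: seal numbers rise steeply with area on small floes,
rise only weakly between the breakpoints, and plateau on the largest floes.

## Worked example

```python
import numpy as np
from floeseal import SegmentedModelSpec, simulate_survey_table
from floeseal.experiments import fit_survey

truth = SegmentedModelSpec.default()
survey = simulate_survey_table(60_000, truth, seed=1)
fit = fit_survey(survey, n_breakpoints=2)
print(fit.summary())
```

prints (abridged):

```
Segmented NB2 GLM (log link)
========================================================
term                                coef        se
const                             -7.568     0.112
rough_1000                       0.04288   0.00134
sic_750                          -0.7237    0.0763
colony_dist                    7.088e-07  6.67e-08
area                              0.1378    0.0018
hinge_1                          -0.1347   0.00183
hinge_2                        -0.003025  0.000128
breakpoint_1 (area)                49.87     0.369
breakpoint_2 (area)                442.1      22.2
theta                             0.5176    0.0107
per-segment slopes: 0.1378, 0.003089, 6.361e-05
loglik -29040.80   AIC 58101.60   converged True
```

Reading this: on floes below ~50 m² each extra m² multiplies the expected
count by e^0.138 ≈ 1.15; past the first breakpoint the rise nearly stops
(slope ≈ 0.003), and past ~480 m² it plateaus. Denser surrounding ice
*lowers* haul-out (SIC coefficient ≈ −0.72) while rougher seafloor raises it;
θ ≈ 0.5 reflects the strong overdispersion of group sizes. All generating
values sit within a couple of standard errors.

There is also a CLI mirroring the pipeline stages
(`floeseal simulate|features|fit|select|predict|report|run`), e.g.

```sh
floeseal run --config config.yaml --seed 1 --out runs/demo
```

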