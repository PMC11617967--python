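# Methods

## Model

Postharvest water loss is modelled as quasi-static Fickian diffusion of
water vapour from the intercellular air of the produce to the ambient air,
across two resistances in series:

```
E = (x_p − x_a) / (r_T + r_B) = Δx / r_tot
```

with `E` the area-related transpiration rate [mg cm⁻² h⁻¹], `x_p` and `x_a`
the volume-related water-vapour concentrations [g m⁻³] of the produce
interior and the ambient air, `r_T` the tissue resistance and `r_B` the
boundary-layer resistance [s cm⁻¹]. The model assumes:

* **Near-saturated interior.** The intercellular air of fresh, non-wilted
  produce is at the equilibrium humidity set by the tissue's water activity;
  `x_p` is evaluated at the produce temperature and `100·a_w` % rH.
* **Quasi-static transport.** Fractional mass loss per protocol is well
  below 1 %, so the resistances, area and interior state are treated as
  constant over one measurement.
* **Produce temperature is an input.** Evaporative cooling depresses the
  surface temperature below the air temperature, particularly in dry air;
  this effect is *not* predicted. The produce temperature should be measured
  (infrared), and defaults to the mean air temperature with a logged
  assumption when it is not.
* **Series network.** Flux continuity holds through the network: with the
  surface concentration `x_pS` from `E = (x_pS − x_a)/r_B`,
  `(x_p − x_pS)/r_T = (x_pS − x_a)/r_B = E/3.6`.

### Units

Concentrations in g m⁻³, rates in mg cm⁻² h⁻¹, resistances in s cm⁻¹. These
units force `r = 3.6·Δx/E`; the factor is the single constant
`RESISTANCE_UNIT_FACTOR` (g m⁻³ = µg cm⁻³ and mg cm⁻² h⁻¹ = 1000/3600
µg cm⁻² s⁻¹), with a dedicated unit test.

### Psychrometrics

Saturation vapour pressure uses the rational-exponential fit
`p_sa = exp[(6.4142801 + 0.0996709·T)/(1 + 0.004197225·T)]` (Pa, T in °C),
which agrees with steam-table references to ~0.1 % between 0 and 30 °C. It
is accepted on −10…+50 °C only — the postharvest range — and raises outside
it rather than extrapolating an empirical fit. Gas constants are the
standard moist-air values Ra = 287.058 and Rwv = 461.52 J kg⁻¹ K⁻¹
(Ra/Rwv = 0.62198). The volume-related water content is computed literally
as `x* = x_a·ρ_a` with ρ_a the *moist*-air density; this is the method's
definition and is deliberately not "corrected" to a dry-air basis.

The inverse solve (humidity from `x*`) iterates the fixed point on the
vapour pressure — `x_a = x*/ρ_a`, `p_da = p_bar·x_a/(ε + x_a)`, refresh ρ_a —
to 10⁻⁹ relative tolerance, max 100 iterations; the density varies by <2 %
over the humidity range so convergence takes a handful of iterations.
Inputs above saturation raise a supersaturation error; results are clipped
to 100 % only against floating-point overshoot at exact saturation.

### Surface areas

Seven produce types carry calibrated linear regressions of surface area on
fresh mass and simple dimensions, with coefficients stored verbatim in a
versioned YAML data file along with mass range, R² and sample count.
Outside the calibrated mass range the regression still evaluates but a
`CalibrationRangeWarning` is attached — the fits are empirical and carry no
extrapolation guarantee. The two 90°-rotated transverse-diameter
measurements (d3) are averaged before use. A user-supplied measured area
always overrides the regression. The bell-pepper regression is treated as an
opaque calibration (whether it includes the internal cavity is unknown).

### Protocols and partitioning

* `free` — authentic boundary layer; `r_T = r_tot − r_B,default`. The
  4.0 s cm⁻¹ default applies to individual apples only; for other species
  the user must supply `r_B` or run a difference protocol.
* `forced` (>2 m s⁻¹) and `wetted` (water film + surfactant) — both are
  taken to null the boundary-layer term, so `r_tot = r_T`. No residual-r_B
  correction is applied for finite airflow.
* difference — `r_B = r_tot,free − r_tot,stripped`, same fruit, same
  temperature.
* `bulk` — `r_B = r_tot,bulk − r_T` with `r_T` known from a prior
  individual measurement; `ProtocolConfig.tissue_resistance_s_cm` carries
  that input. Bulk boundary-layer resistances are an order of magnitude
  above single-fruit values (restricted air exchange).

A negative `r_T` or `r_B` is always an error naming both operands, never a
silent clamp: it signals inconsistent protocol or climate data.

### Estimators and climate averaging

The default rate estimator differences the first and last weighings
(`endpoint`); an OLS slope of mass vs time (`slope`) is available for noisy
dense series. The ambient state is one psychrometric evaluation of the
time-weighted (trapezoidal, piecewise-linear) mean temperature and humidity
over the weighing window — a small-fluctuation approximation, exact for
constant climate. Recommended minimum durations: 24 h for individual fruit,
48 h for packaged/bulk (configurable).

### Temperature dependence

Resistances are temperature-dependent and should be measured at the
temperature of interest; for approximate translation the Arrhenius form
`r(T) = r_ref·exp[(E_a/R)(1/T − 1/T_ref)]` is provided, with E_a estimated
as the least-squares slope of ln r vs 1/T (≥2 distinct temperatures; no
default E_a). Fitted to the measured apple anchors (391 s cm⁻¹ at 20 °C,
750 s cm⁻¹ at 1 °C) this gives E_a ≈ 22.9 kJ mol⁻¹ and a cold/warm ratio of
1.92 — the roughly twofold rise seen in cold storage.

## Synthetic-data generator

`simulate.forward_simulate` integrates `dm/dt = −E(t)·A` with explicit
1-minute steps (the dynamics are quasi-static; nothing stiffer is
warranted), samples the trajectory on the weighing schedule, rounds to the
balance resolution (0.1 mg default, matching the precision balance the
method prescribes), and writes the climate log at its own cadence. The
surface area is held at its initial value (losses <1 % of mass). Climate
drift is an optional stationary AR(1) perturbation of temperature and
humidity, off by default: the reference conditions are a climatised room at
20 °C / 50 % rH (individual apples: r_T = 391, r_B = 4.8 s cm⁻¹, 24 h, 2 h
weighings; bulk: r_T = 363, r_B = 50.4 s cm⁻¹, 72 h, daily weighings). In
population experiments each seed draws one fruit mass from the studied lot,
131 ± 20 g, truncated to the regression's calibrated range.

What the generator emulates: the deterministic series-resistance physics,
balance quantization, slow climate drift, and the paired/bulk experimental
designs. What it does not: biological variability of r_T within a fruit lot,
the near-linear growth of r_T over storage time, evaporative surface
cooling, respiration heat and mass effects, and handling artefacts
(condensation on cold fruit). Passing recovery tests therefore demonstrate
the correctness of the estimation chain, not the field accuracy of the
assumptions on real produce.

`recovery_experiment` runs the matching estimation protocol against the
generator's truth: noiseless runs recover the injected resistances to
floating-point precision for all four protocols; with 0.1 mg quantization
and 2 h weighings over 24 h the per-run tissue-resistance error stays below
the quantization bound (~0.03 %, two endpoints of ±0.05 mg against ~370 mg
of daily loss) and the 100-seed mean is unbiased (round-to-nearest noise is
centred).

## Defaults that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| water activity a_w | 0.985 | – | fresh-apple equilibrium humidity 98.5 % |
| free-convection r_B | 4.0 | s cm⁻¹ | individual apples; negligible error when r_T > 150 s cm⁻¹ |
| barometric pressure | 101325 | Pa | standard atmosphere, substituted with a logged warning |
| balance resolution | 0.1 | mg | precision balance used by the protocol |
| weighing interval / duration | 2 / 24 | h | individual-fruit protocol |
| bulk duration | 48–72 | h | slower relative loss in packaging |
| Arrhenius R | 8.314 | J mol⁻¹ K⁻¹ | universal gas constant |

Every default actually used in a run (assumed r_B, fallback pressure,
substituted produce temperature) is recorded in the result's provenance and
in the run log — the method's credibility rests on exposing its assumptions.

## Known limitations

* The surface-humidity inversion uses the produce temperature when supplied
  and the air temperature otherwise; the choice is recorded in provenance.
* Packaging films are handled only implicitly, as an added series
  resistance folded into the bulk r_B; film permeance is not modelled.
* The published resistance table ships as a reference fixture for context
  and cross-checks; raw laboratory weighings behind it are not available,
  so those values are anchors, not reproducible outputs.
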