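# Methods

This note documents the models implemented in `moonsim`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish.

## Ephemeris

Positions come from a medium-precision analytic theory: the ~60 leading
periodic terms of the ELP-2000/82 lunar solution (longitude/distance and
latitude series plus the venus/jupiter/flattening additives) and the
standard low-order solar theory, with nutation truncated to its two leading
terms.  Internal accuracy is a few hundredths of a degree for the Moon and
better than 0.01° for the Sun.  The design contract is 0.5° — an order of
magnitude looser — because the downstream brightness model is far more
sensitive to its own photometric parameters than to arcminute-level
geometry.

Verification uses three independent routes in the test suite: frozen
textbook worked-example positions (1992 anchors for the lunar and solar
series and the phase angle), published almanac events (four 2020 full-moon
instants, matched by the phase-angle minimum to within an hour), and a
second, fully independent low-precision theory (Astronomical Almanac-style
few-term series with its own sidereal-time and altitude formulas) with
maximum disagreement below 0.3° over 10 000 random instants of 2020.

Decisions:

* **Time scales.** Everything is computed in UTC; the lunar/solar series
  take terrestrial time via a ΔT polynomial valid for 2005–2050 (clamped
  outside).  A few seconds of ΔT error moves the Moon by ~0.002°.
* **Phase angle is geocentric** (Sun–Moon–Earth centre).  The topocentric
  phase angle can differ by up to ~1°, but the geocentric convention is what
  illumination models and almanac "full moon" instants use, and it keeps α
  identical across observing sites.
* **Parallax.** The Moon's altitude is corrected topocentrically by the
  standard h′ = h − π·cos h with π = asin(R⊕/Δ); the sub-0.01° residual of
  the full rigorous treatment is irrelevant at the contract level.
  Elevation defaults to 0 m (the site is at sea level).
* **Refraction** enters only the rise/set definition (−0.8333° for the
  refracted upper limb); reported altitudes are unrefracted geometric
  values, because the brightness model wants geometric zenith distance.
* **Rise/set** is found by scanning the UTC civil day at 1-minute
  resolution and interpolating the horizon crossing; days without a
  crossing raise an explicit `PolarDayNight` signal.

## Zenith sky brightness

The moonlit zenith sky is modeled with the classical scattered-moonlight
treatment: lunar magnitude from the phase polynomial
m(α) = −12.73 + 0.026 α + 4·10⁻⁹ α⁴, flux I\* = 10^(−0.4(m+16.57)),
a Rayleigh+Mie scattering function f(ρ) = 10^5.36(1.06+cos²ρ) + 10^(6.15−ρ/40)
evaluated at ρ = Z_moon (the zenith is the observed sky point), scattered-light
airmass X(Z) = (1−0.96 sin²Z)^(−1/2), and extinction along the lunar path with
re-scatter toward the zenith:

B_nl = f(ρ) · I\* · 10^(−0.4 k X(Z_moon)) · (1 − 10^(−0.4 k X(0))).

Two multiplicative corrections are applied to I\*:

* **Opposition surge.** The phase polynomial alone under-predicts the full
  moon: near opposition the lunar surface brightens nonlinearly, by a
  factor of about 1.3 at α = 0.  The polynomial carries no explicit surge
  term, so one is added: a linear ramp from `opposition_peak` (1.3) at
  α = 0 to 1 at `opposition_cutoff_deg`.  The surge is confined to phase
  angles of a few degrees; within that plausible range the cutoff was
  calibrated to 5.0° so that, with the default extinction, the modeled peak
  of the 2 Feb–2 Mar 2020 window reproduces the study system's reported
  maximum nightly illuminance of 0.39 lx.  (At a 7° cutoff the same
  computation gives 0.41 lx; the choice moves only the relative weight of
  the near-full nights.)
* **Distance.** Flux scales by (384 400 km / Δ)², the photometric
  counterpart of the parallax/distance variation over the anomalistic
  month (~±7% in flux).

Other parameters:

* **k = 0.30 mag/airmass.**  The model's original fit (0.172) describes a
  4200 m observatory; a sea-level maritime site sits near 0.25–0.35.
  Configurable.
* **Night threshold −6°.**  The moonlight channel is dark whenever the sun
  is above civil-twilight end, because the physical moon LEDs are off by
  day and twilight is excluded from observation.  The astronomical quantity
  remains computable for any geometry via `zenith_moon_brightness`.
* **Normalization instead of absolute photometry.**  Converting nanolamberts
  at the zenith to horizontal illuminance in lux would require an absolute
  calibration and a whole-sky integral the system does not need: the lamp
  bank is driven by a relative duty cycle.  The series is therefore scaled
  so the brightest minute of the normalization window (calendar 2020 by
  default) equals `norm_peak_lux` = 0.5 lx, and "lux" means exactly that
  calibrated scale.  Under the defaults the annual peak minute falls in the
  night of 30 December 2020 (a high-declination winter full moon at small
  phase angle), and the experimental window peaks on the night of
  8–9 February at 0.3936 lx (0.39 at 2 d.p.), 79% of the annual maximum.

Degenerate inputs: the brightness is defined as 0 whenever the Moon is at
or below the geometric horizon; a normalization window with no moonlight is
rejected rather than producing infinities; ρ = 0 (observing the lunar disc
itself) is outside model scope and rejected, which in practice requires the
Moon at the exact zenith — unreachable at the site's latitude.

## Schedules and sampling plan

Each chamber's minute table drives three channels: daylight strictly
between local sunrise and sunset; the moonlight duty cycle
(100 × normalized index, forced to 0 in daylight); ALAN exactly when the
daylight channel is off ("dusk-to-dawn" — the physical photocell switches on
at darkness), at the chamber's fixed illuminance.  Moonlight and ALAN are
simultaneously active at night, matching the additive light environment of
the physical chambers.  Schedules are pure functions of the configuration —
re-running produces identical bytes.

The sampling plan encodes the observation arithmetic: inclusive endpoints
give span·60/interval + 1 frames (289 for 5 min/24 h), nights are every
second night of the 28-day period with a configurable dropped set (default:
night 21, lost in the study to a charging error), leaving 13 nights and
289 × 7 × 12 × 13 = 315 588 frames.

## Synthetic foraging generator

The generator reproduces the experimental layout — 7 treatments × 3 tanks
× 4 snails × 13 nights × 2 time-of-day strata = 2184 Bernoulli records —
under

logit p = β₀ + β_alan[t] + β_moon[t]·moonlux + γ·night + u_tank + u_snail,

with u ~ N(0, σ²) independent at the two levels and the nightly-maximum
moonlight covariate shared by both strata of a night (the day stratum of an
observation video experienced the same lunar night as its night stratum).
The default covariate values are the package's own modeled nightly maxima
for the 13 observation nights (0.0391, 0.1009, 0.2217, 0.3936, 0.1889,
0.0645, 0.0197, 0.0054, 0.0011, 0, 0.0001, 0.0007, 0.0046 lx).

The default "reversal" scenario sets β_moon = (−3, 0, 0, 0, +3, +3, +3)
logit/lx for (control, 0.1, 0.5, 1, 10, 10-mit, 50 lx), β₀ = −0.3,
γ = 0.01, σ_tank = 0.25, σ_snail = 0.5.  The magnitude ±3 was calibrated by
simulation at the study's sample size: it is the smallest round value at
which the ALAN × Moonlight interaction test comfortably exceeds 80% power
(≈0.94 over 200 runs) while the control and 50 lx slope signs are recovered
in ≥95% of runs.  Random slopes, overdispersion, within-night movement and
temporal autocorrelation are all outside the generator: passing tests show
the workflow recovers effects of this form at this design size, not that
real foraging data satisfy the Bernoulli-with-random-intercepts model.

## Statistical workflow

* **Global GLM and selection.**  The global fixed structure is
  ALAN\*Moonlight + ALAN\*Night + ALAN\*TimeOfDay.  All 35
  marginality-respecting submodels are fitted by IRLS; the table is ranked
  by AIC (= −2ℓ + 2k; AICc available by changing one line was deliberately
  not added — AIC matches the workflow being mirrored) with Akaike weights
  exp(−Δ/2) normalized to 1; the reported candidate set is the smallest top
  set with cumulative weight ≥ 0.99, and "best" is its lowest-AIC member.
  Non-convergent submodels are excluded with a warning, never silently.
* **GLMM.**  Random intercepts for tank and snail-within-tank; snail ids
  are globally unique (`treatment:tank:snail`), so nesting reduces to two
  crossed-coded intercept blocks.  Fitting is Laplace-approximate ML: for
  fixed (σ_tank, σ_snail) the joint penalized Bernoulli log-likelihood is
  maximized over all fixed and random coefficients by damped Newton (PIRLS),
  and the profiled Laplace log-likelihood
  ℓ = ℓ_cond(û) − ½û′D⁻¹û − ½log|D| − ½log|Z′WZ + D⁻¹| is maximized over
  the two log-σ by Nelder-Mead.  This is the same approximation `glmer`
  uses at nAGQ = 1; on a reference dataset the test suite demands agreement
  with `lme4` to 0.1 in log-likelihood and a few percent in coefficients.
  Fits with a variance component under 10⁻³ are flagged singular and still
  reported.  Reported coefficient covariance is the fixed-effect block of
  the inverse penalized joint Hessian (what `glmer`'s `vcov` returns).
* **Type III tests.**  Each term of the selected model is dropped singly —
  main effects in the presence of their interactions, under treatment
  coding — and the nested fits compared by likelihood ratio,
  χ² = 2Δℓ on the parameter-count difference (6 d.f. for any
  ALAN-involving term, 1 otherwise).  This mirrors the stepwise Type III
  convention of the mixed-model R ecosystem; it makes main-effect tests
  contrast-dependent, which is inherent to Type III and documented rather
  than hidden.  Null simulations in the acceptance suite verify each term's
  rejection rate at nominal 0.05 lies in [0.03, 0.07] over 500 seeded
  datasets.
* **Moonlight slopes.**  The slope for treatment t is the Moonlight
  coefficient plus t's interaction coefficient (an estimated marginal
  trend); standard errors come from the coefficient covariance, and all 21
  pairwise differences are reported with unadjusted two-sided normal
  p-values (adjustment deliberately off by default, mirroring the analysis
  convention being reproduced; any of scipy's corrections can be applied to
  the returned p-values).
* **Prediction intervals.**  Simulation-based: draws from N(β̂, V̂)
  propagated through the inverse link, optionally adding a random-intercept
  draw with the estimated total standard deviation; the point prediction is
  the inverse-logit at β̂ and is clamped inside the reported interval.
  Moonlight values beyond the fitted range are flagged, not rejected.

## Problem sizes used in the tests

The acceptance suite computes the full calendar-2020 series at 1-minute
resolution (527 040 samples, ~30 s), compares 10 000 random instants
against the independent ephemeris, and runs 500-seed null simulations and
200-seed recovery simulations through the GLM route of the workflow (the
GLMM route is exercised on single datasets and against `lme4`; running
hundreds of mixed fits would add nothing but optimizer time, as the two
routes share the term-testing machinery).  Monte-Carlo reference rates
quoted in test docstrings (e.g. the 0.795 within-2-AIC rate for null data)
were computed with the same generator at 200 seeds.

## Known limitations

* No spectral model: the moonlight channel carries intensity only; the
  natural spectral shift of moonlight with phase and elevation is not
  simulated, and the 510 nm mitigation filter is a metadata flag on the
  treatment, not a radiative computation.
* No twilight simulation; the night threshold is a hard −6° gate.
* No clouds, aerosols, airglow or starlight background: the brightness is
  the clear-sky lunar contribution at the zenith point only.
* The opposition surge is a phenomenological ramp anchored at 1.3×/5°; the
  true surge shape is nonlinear and wavelength-dependent.
* The lux scale exists only relative to the normalization; comparisons to
  photometer readings require an external calibration.
* The GLMM is random-intercept only, by design; random slopes or
  overdispersion require a different tool (e.g. glmmTMB).
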