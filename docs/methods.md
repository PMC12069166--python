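# Methods

## Scope and intent

`ecocap` is a zero-dimensional (single well-mixed box), deterministic,
discrete-time food-web simulator built to study one question: how
aggregate multispecies fishery yield relates to an ecosystem-level catch
cap when climate forcing and predator–prey interactions are in play. It
deliberately trades away the machinery of full end-to-end ecosystem
models — spatial cells, hydrodynamics, nutrient cycling, fleets — so
that the complete experimental design (a 156-run per-stock F_MSY
profiling step plus a 52-run multispecies scenario grid) executes in
minutes. Results on the bundled synthetic webs are therefore
qualitative analogues of what a spatially explicit calibrated ecosystem
model would produce, not predictions for any real system.

## State and dynamics

State comprises numbers-at-age `N[g,a]` and weight-at-age `W[g,a]` (kg)
for age-structured groups (fish and endotherms), and biomass `B[g]` (t)
for logistic pools. Age classes are 1-based and may span
`years_per_age` calendar years for long-lived species; the oldest class
is a plus group. The default sub-annual step is Δt = 1/12 yr — the
target quantities are last-five-year equilibrium means, not sub-daily
dynamics, and halving Δt changes those means by well under the
tolerances used anywhere in the test-suite.

Each step applies, in order: consumption, Baranov mortality with
knife-edge selectivity, growth relaxation, and the pool update. At each
year boundary cohorts age (every `years_per_age` years), spawning
biomass is evaluated on the post-aging structure, and recruits enter
class 1.

### Temperature linkages

Three distinct mechanisms link temperature to the biology; all use the
regime's daily climatology (monthly means for the within-year steps,
the annual mean for the spawning gate).

1. **Bioenergetic consumption scaling** `f(T)`: the unimodal
   thermal-performance form `f = V^X e^{X(1−V)}`,
   `V = (T_max−T)/(T_max−T_opt)`,
   `Z = ln Qc (T_max−T_opt)`, `Y = ln Qc (T_max−T_opt+2)`,
   `X = Z²(1+√(1+40/Y))²/400`; exactly 1 at `T_opt`, 0 at and above
   `T_max`, monotone on each side. Endotherms bypass it (their
   metabolism is not water-temperature forced).
2. **Thermal-habitat suitability** `σ(T)`: a trapezoid over breakpoints
   `[T0,T1,T2,T3]` multiplying foraging demand. This is the 0-D
   collapse of a spatial thermal niche: warming does not move animals
   here, it shrinks the fraction of their foraging opportunity that is
   thermally suitable.
3. **Spawning-temperature gate** `g(T)`: a trapezoid that is 1 on
   `[T_lo,T_hi]` and tapers linearly to 0 over width τ (default 1 °C;
   τ = 0 gives a hard gate). The paper-style mechanism of stenothermic
   reproduction: a narrow window plus a warm climatology produces
   complete recruitment failure.

### Trophic interactions

The functional response is a multispecies Holling type II with a shared
half-saturation per predator: demand
`D = Cmax·f(T)·σ(T)·W·N·Δt`, prey field `φ = Σ_p a_p B_p / H`,
realized intake `D·φ/(1+φ)`, allocation across prey ∝ availability ×
biomass. No ecosystem engine publishes "the" correct response at this
scale; type II with biomass-proportional allocation is the simplest
form that produces realized diet shifts as prey fields change.
Aggregate removal from any prey is capped at 90% of its standing stock
per step with proportional rescaling of all flows onto it — a
positivity guarantee chosen over an implicit solver. Realized flows are
converted to an instantaneous predation mortality
`M2 = removal/(B·Δt)` applied uniformly across prey ages (equivalently:
removal distributed ∝ biomass-at-age).

### Growth and reproduction

Weight-at-age relaxes toward a ration-scaled reference,
`W' = W + κ(ρ W_ref − W)Δt`, `κ = 1 yr⁻¹`, `ρ` = realized/demanded
intake (1 when demand is 0). Sustained full rations drive cohorts to
the reference growth curve; sustained rationing to `ρ·W_ref`. Fish
recruit through a Beverton–Holt curve in steepness form
(`R(S0) = R0`, `R(0.2·S0) = h·R0`) times the spawning gate; `S0` is
derived at validation time as `R0` × the unfished spawning biomass per
recruit of the group's own decoupled equilibrium, so an unfished,
fully rationed stock sits exactly at `(S0, R0)`. Endotherms instead
reproduce at `R0` × their annual mean body-condition ratio: the
mechanism by which prey depletion becomes top-predator decline is
weight-at-age and fecundity, not starvation mortality.

### Fishing

Time-invariant instantaneous F with knife-edge selectivity at
`age_select`, constrained at configuration time to be ≤ the age at
first maturity (avoiding the artificial productivity that arises when
young spawners are unfished). Calibration fishing is ¼F_OFL for stocks
with an assessment F_OFL and ¼M otherwise; endotherms are never fished.

## Forcing

A regime is one 365-day temperature climatology plus per-group
productivity scalars, looped so that every same-day-of-year statistic
has zero interannual variance. Projected regimes are built by delta
correction `x' = x̄_hind + (x_proj − x̄_hist)` applied at daily
resolution, collapsed to a climatology over the projection years, with
productivity halved for the plankton pools (the documented association
between warm conditions and low lower-trophic productivity). The
synthetic generator's "climate model" series is the historical sinusoid
(mean 7 °C, amplitude 4 °C) plus a uniform warming delta (default
2.5 °C), a constant 0.6 °C model bias, and mean-zero interannual
offsets; bias and offsets cancel exactly through the
correction-plus-climatology pipeline, so the corrected warming equals
the configured delta. Salinity and transport have no 0-D analogue and
are not represented.

## Simulation protocol and experiment

Runs are 80 years: a 30-year burn-in under calibration fishing and the
historical regime, then an abrupt switch to the scenario fishing policy
and regime. Outputs (catch, SSB, biomass, numbers-at-age, diet flows)
are recorded annually; "equilibrium" is operational — the mean over the
final five years, with CV = sd/mean (sample sd, defined 0 at zero
mean). No convergence criterion is imposed; divergence detection is by
non-finite state only.

Step 1 profiles each focal group over 13 evenly spaced F values from 0
to 4·F_OFL (spacing is a design choice; the endpoints are both
meaningful, multiplier 0 supplying the unfished baseline). F_MSY is the
grid argmax of equilibrium catch, ties broken toward the smallest F,
boundary argmaxes flagged. Step 2 reuses the same 13-value multiplier
grid on the MF_MSY vector under four scenarios (historical/projected ×
predator full/underexploited); under the underexploited policy the key
predator's F is pinned at ¼F_OFL at every multiplier, including 0, so
that the policy contrast is constant across the grid. Burn-in always
uses calibration fishing.

## Evaluation metrics

Aggregate yield sums last-five-year mean catches over cap-countable
focal groups (the halibut-like group is focal but excluded, matching
how halibut sits outside the groundfish cap); attainment uses ≥ at the
boundary. B35% counts compare each focal stock's SSB with 35% of an
unfished reference; the default reference is the same scenario's
multiplier-0 run (isolating fishing effects from climate effects), with
the historical-climate baseline available as a switch (measuring
combined climate + fishing depletion — under a warm regime a
climate-collapsed stock is only "below B35%" against this baseline,
since against its own scenario's unfished run the multiplier-0 cell is
identically 1). Indirect effects report, per forage group, the % change
in total biomass of its predators versus the unfished run (and per top
predator, of its prey), with link sets derived from diet availabilities
> 0. Realized diet compositions are normalized flow totals over the
final five years.

## Synthetic webs

`toy3` is a three-group chain (predator fish, prey fish, plankton) with
closed-form decoupled equilibria, used as the universal test fixture.
`goa_like` is a 26-group web: 12 focal groundfish (the 11 published
Gulf-of-Alaska assessment F_OFL values, 0.06–0.51 yr⁻¹, plus a
halibut-like group at its natural mortality 0.2 yr⁻¹, fished but not
cap-countable), five forage-fish groups, three plankton pools plus
benthos, and five endotherm predator groups. Life-history parameters
(ages, growth curves, maturity, M, steepness, thermal windows) are
deterministic plausible-range choices — the recipe seed adds only a
small (≤5%) jitter to growth and thermal coefficients. Unfished
recruitment R0 is calibrated so each group's *decoupled* equilibrium
hits a documented biomass target of realistic Gulf-of-Alaska magnitude
(e.g. 900 kt pollock SSB); with trophic links active the web settles
below those targets, which is the intended baseline state.

The diet matrix encodes the study's mechanisms by construction: the
arrowtooth-like predator's largest fish-prey availabilities are on the
pollock-like and cod-like stocks (top-down control, scalable via
`predator_strength`); forage fish feed on plankton (bottom-up food
limitation under the warm regime); sea-lion-like endotherms rely on
groundfish while dolphin-like ones rely on forage fish (divergent
indirect responses to groundfish removals). The cod-like spawn window
(3–8.5 °C, τ = 0.5) closes under the default projected climatology
(annual mean 9.5 °C). Availability magnitudes and half-saturations
(set so the unfished prey field gives φ ≈ 10, i.e. ~91% rations) were
chosen so that total predation mortality on any groundfish stays near
0.1 yr⁻¹ — strong enough that predator release is clearly visible
(fishing arrowtooth down raises pollock-like equilibrium SSB by
~15–20%), weak enough that an unfished 80-year run keeps every group
within [0.5×, 2×] of its initial (decoupled-equilibrium) biomass, a
stability gate enforced in the tests.

What the generator does *not* emulate: recruitment variability and
regime shifts, ontogenetically resolved prey ages, movement and
distribution shifts, bycatch and fleet structure, and any calibration
to observed time series. Passing tests therefore demonstrate the
mechanisms and the experiment logic, not skill against data.

## Numerical choices and degenerate inputs

- Monthly Baranov survival with constant annual rates telescopes
  exactly to the annual closed form, which is what makes the
  single-stock yield-per-recruit oracle an exact cross-check
  (tolerances there reflect only finite spin-up, < 0.5%).
- The decoupled-equilibrium helper iterates the exact annual
  survival–growth–aging recursion (including plus-group blending and
  multi-year classes) to 1e-13 relative convergence; it is also the
  initial condition for every run.
- Ties in F_MSY selection break toward the smallest F (argmax-first on
  the grid); a collapsed stock with identically zero catch therefore
  reports F_MSY = 0.
- Zero-mean CVs are defined 0; zero-unfished-SSB groups are excluded
  from B35% counts with a warning; empty indirect-effect link sets are
  reported not-applicable (NaN).
- Pools are floored at 0 after losses with a depletion warning; prey
  removal is capped at 90% per step as above.
- The model is deterministic: the run seed only drives optional
  initial-condition jitter (off by default), and the recipe seed only
  the generator's small parameter jitter.

## Problem sizes

The default experiment is 156 Step-1 runs plus 52 Step-2 runs of
80 years at Δt = 1/12 on a 26-group web, about two minutes on one CPU;
the test-suite exercises the same design on the 3-group toy web and
runs the full default experiment once for the directional checks. The
stability gate runs at 40 years inside the unit suite and the full 80
years in the acceptance path.

## Known limitations

Single box, so no spatial refugia or distribution shifts; uniform-age
M2, so no size-structured predation windows; shared half-saturation per
predator, so no prey switching beyond biomass proportionality;
time-invariant F with no harvest control rules, discards, or fleet
dynamics; endotherm demography is condition-driven and deliberately
simple. The cap evaluation is an accounting of model output, not a
management simulation: it reports whether aggregate equilibrium yield
can reach a cap, not how a council process would respond.
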