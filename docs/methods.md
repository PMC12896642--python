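# Methods

## Scope and intent

`pigflux` is a forward simulator of diurnal live-weight dynamics in
finishing pigs of roughly 100 kg. It does not predict individual animals;
it quantifies the *order of magnitude* of within-day weight fluctuation
that normal drinking, feeding, urination and defecation produce, as a
reference for interpreting discrepancies between instantaneous floor-scale
readings and morphology-based (camera) weight estimates.

## Model structure

Each pig-day is simulated independently on a 1-min grid over 24 h
(grid points 0..1440 inclusive, so the endpoint exists for the exact
growth-constraint check). Live weight is

    W(t) = W0 + W_water(t) + W_GI(t) + W_urine(t) + W_feces(t) + g(t)

where `g(t) = c·t` is an affine growth correction with
`c = (daily_gain − (R(1440) − R(0))) / 1440` applied to the raw component
sum `R`. The additive affine form is the unique choice that pins the net
24 h change to the +0.8 kg daily-gain target while shifting every lag-L
difference by the same constant `c·L`, i.e. preserving the temporal
structure of short-term variability (rescaling events would not).

### Drinking

Bout count: Poisson(11) truncated to {8..15} by rejection (equivalent in
law to renormalised-pmf sampling, and simpler). Bout size: gamma(shape 6,
scale 0.15 kg) truncated to [0.4, 1.6] kg by rejection — mode ≈ 0.75 kg,
mean ≈ 0.9 kg, most mass inside the bounds. A rejection loop exceeding
10 000 draws raises an "infeasible configuration" error (the distribution
puts essentially no mass inside the truncation bounds). Each bout adds its
mass instantaneously and decays linearly to zero over a fixed 180-min
clearance window; overlapping bouts superpose.

### Feeding and gastrointestinal fill

Daily feed uniform on [2.5, 3.0] kg, split over a uniform 3–6 meals by a
symmetric Dirichlet(α = 4) — moderate variability among meals without the
near-equal split of large α or the one-meal-dominates extreme of small α.
Each meal adds `feed × 1.15` (a 15 % water-binding component) to the GI
compartment, which empties linearly over a fixed 12-h transit time. Meal
times use the same circadian rule as drinks; no minimum inter-meal spacing
is enforced.

### Elimination reservoirs

Urine and feces accumulate at constant rates equal to
`daily_total / 1440` kg/min; defaults 4.0 kg/day urine and 1.5 kg/day
feces, physiologically plausible for a 100 kg finishing pig and exposed in
the configuration (the urine total is also swept in the sensitivity
analysis). Event counts are uniform on {6..10} (urination) and {2..4}
(defecation). Per-event removal *targets* are Dirichlet(α = 4)-allocated
shares of the daily total, so expected removals match accumulation by
construction; the realised removal at trajectory time is
`min(target, current reservoir level)`, which keeps the level non-negative
with probability 1. Reservoirs start empty at 00:00 by default; a
steady-state initialisation (half the mean inter-event content) is
available via `reservoir_initial_steady_state`. Either way the growth
correction absorbs the endpoint mismatch, so the choice mainly affects the
first hours of the trajectory.

The four components are mutually independent: cleared drinking water is
*not* routed into the urine reservoir, and excretion rates are fixed
constants rather than functions of intake. This mirrors the model being
reproduced; imposing a global water balance would change the fluctuation
statistics and is deliberately out of scope.

### Circadian event timing

Every event time is a two-level mixture: with probability 0.85 uniform on
the daytime grid [06:00, 22:00), otherwise uniform on the night grid. The
day/night contrast is only qualitatively constrained by behaviour
("higher probability during daytime"); 0.85 is the calibrated default.

### Conventions

* Event times are integer grid minutes; two events of one kind may share a
  minute (magnitudes add).
* The series value AT an elimination minute is post-removal; at a
  drink/meal minute it is post-jump.
* All kinetics are evaluated in closed form at each grid point — no
  numerical integration — so halving the time step changes no value at
  shared grid points.
* Percentiles use linear interpolation between order statistics
  (`numpy.percentile` default).
* Randomness: one root seed; independent deterministic substreams per
  (pig, event kind) via `numpy.random.SeedSequence([seed, pig_id, kind])`.
  Adding pigs never perturbs earlier pigs' draws, and perturbing one event
  kind's parameters leaves all other kinds' draws bit-identical — the
  basis of the paired sensitivity design.

## Per-pig and population outputs

Per pig: fluctuation range `max W − min W`; largest absolute change over
60- and 120-min lags; largest single-minute increase/decrease; and band
exceedance — whether `|W(t) − reference|` ever exceeds a half-width
(±2 and ±3 kg by default). The reference is the pig's daily time-mean
weight, standing in for the stable structural mass a shape-based estimator
tracks; `exceedance_reference: growth_line` switches to the
baseline-plus-growth line. Population aggregation reports the mean,
median and 25th/75th percentiles of the range distribution and the
exceedance fractions; fewer than two pigs is an error rather than a
silently degenerate percentile.

## Sensitivity analysis

One-factor-at-a-time: drinking clearance window ∈ {120, 180, 240} min,
GI transit ∈ {480, 720, 960} min, urination magnitude scale ∈
{0.5, 1.0, 1.5}× (applied to the daily urine total, which scales every
per-event target). Each row is a full population run with the same root
seed, so rows are paired: kinetic parameters leave every event schedule
identical, isolating the parameter's effect.

## Calibration

Parameters fixed by physiology (counts, size bounds, daily totals,
clearance/transit windows, +0.8 kg/day gain, 1000-pig population) are
hard defaults. The free parameters — gamma bout-size shape/scale, daytime
probability, both Dirichlet concentrations, excretion totals — were
calibrated once against the target population statistics (mean range
4.2 kg, IQR 3.4–5.1 kg) and then frozen; the shipped defaults are the
first-choice plausible values listed above, which already reproduce the
mean to within ~0.1 kg across seeds. The simulated IQR (≈ 3.5–4.8 kg) is
somewhat narrower than 3.4–5.1 kg: the spread of the range distribution is
dominated by event-count stacking, and widening the bout-size or Dirichlet
spread moves it very little, so no further tuning was applied.

## What the simulation does and does not show

The generator emulates event-driven mass flux with simple linear kinetics.
Real kinetics are nonlinear, state-dependent and circadian-modulated; real
drinking responds to temperature and feeding; water actually transits into
urine. Passing tests therefore demonstrate internal consistency and the
order-of-magnitude claim — several kilograms of normal within-day
fluctuation — not fidelity to any individual animal's trajectory. Results
are parameterised for ~100 kg finishing pigs; lighter pigs, heat stress or
different feeding regimes would change the amplitudes.

## Problem sizes

The default population is 1000 pigs × 1441 grid points (< 1 s per run).
The test suite runs populations of 25–1000 pigs, 10 000 single-pig
assemblies for the exact growth-constraint check, and 10 000-draw samples
for the distributional goodness-of-fit checks.
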