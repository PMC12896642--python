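# pigflux

Stochastic simulator of **within-day live-weight fluctuation in finishing
pigs** (~100 kg).

Live weight read off a floor scale is not a stable quantity. Over a single
day a pig drinks 8–15 times (0.4–1.6 kg per bout), eats 2.5–3.0 kg of feed
in 3–6 meals, urinates 6–10 times and defecates 2–4 times. The water and
digesta moving through the animal shift its instantaneous mass by several
kilograms, so a scale reading and a camera-based (morphology-derived)
weight estimate can disagree by kilograms with neither being wrong.
`pigflux` quantifies that physiological noise floor: it simulates
minute-resolution live-weight trajectories for a Monte-Carlo population of
virtual pigs and summarises the within-day fluctuation range against which
weighing-technology accuracy claims should be judged.

## Model

Live weight is the sum of a baseline and four transient mass components:

```
W(t) = W0 + W_water(t) + W_GI(t) + W_urine(t) + W_feces(t)
```

evaluated on a 1-min grid over 24 h, plus an affine growth correction that
forces `W(24 h) − W(0) = +0.8 kg` while preserving short-term structure.

* **Drinking** — bout count truncated-Poisson on {8..15}; bout size
  truncated-gamma on [0.4, 1.6] kg; each bout adds its mass instantaneously
  and clears linearly over 180 min.
* **Feeding** — daily feed uniform on [2.5, 3.0] kg split over 3–6 meals by
  a symmetric Dirichlet; each meal adds feed plus a 15 % water-binding
  component and empties linearly over a 12 h transit time.
* **Elimination** — urine and feces reservoirs fill at constant rates
  matching daily excretion totals (4.0 and 1.5 kg/day by default);
  urination/defecation events instantaneously remove a per-event target
  mass, capped at reservoir content.
* **Circadian timing** — events fall in the daytime activity window
  (06:00–22:00) with probability 0.85, uniformly at night otherwise.

Per-pig statistics are the fluctuation range `max W − min W`, the largest
absolute change over 1 h and 2 h lags, single-minute step extremes, and
whether the trajectory ever leaves a ±2 or ±3 kg band around the pig's
daily-mean weight (the stable quantity a shape-based estimator tracks).

## Worked example

```python
import pigflux as pf

config = pf.SimulationConfig(seed=42)          # 1000 pigs, calibrated defaults
population = pf.simulate_population(config)
print(population.to_dict())
```

prints (abridged):

```
mean_range_kg   4.2006
median_range_kg 4.1105
iqr_low_kg      3.4646
iqr_high_kg     4.8396
exceedance_fraction  {2.0 kg: 0.765, 3.0 kg: 0.260}
```

The mean within-day fluctuation range is ≈ 4.2 kg with an interquartile
range of roughly 3.5–4.8 kg — i.e. a typical 100 kg pig's scale weight
spans about 3–5 kg over one day from normal physiology alone — and 76 % of
pigs drift beyond ±2 kg of their own daily-mean weight at some point, so
instantaneous scale readings routinely leave the ±2–3 kg band quoted as
camera-system accuracy. A single pig:

```python
trajectory = pf.simulate_pig(config, pig_id=0)
summary = pf.summarize_pig(trajectory, config)
# fluctuation_range=3.63 kg, max 1 h change 2.54 kg, max 2 h change 3.12 kg
```

The one-factor-at-a-time sensitivity sweep (`pf.ofat_sensitivity`) reruns
the population with drinking clearance at 2/3/4 h, gastrointestinal transit
at 8/12/16 h, and urination magnitudes scaled ×0.5/1/1.5; the mean range
stays on the kilogram scale in every case.

The same pipeline is scriptable from the shell:

```bash
pigflux simulate --n-pigs 1000 --seed 42 --out-dir out/
pigflux sensitivity --seed 42 --out-dir out/
pigflux summarize out/trajectories/
```

Every output directory includes a `manifest.json` (resolved config, seed,
version) from which the run reproduces byte-identically.

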