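"""Event-schedule sampling: truncation bounds, analytic moments, determinism."""

import numpy as np
import pytest
from scipy import stats

from pigflux import SimulationConfig, sample_schedule
from pigflux.events import (
    kind_rng,
    sample_drink_events,
    sample_elimination_events,
    sample_event_times,
    sample_meal_events,
)

N_SCHEDULES = 10_000


def truncated_poisson_moments(mean, lo, hi):
    """Brute-force mean/var of Poisson(mean) restricted to {lo..hi}."""
    k = np.arange(lo, hi + 1)
    p = stats.poisson.pmf(k, mean)
    p = p / p.sum()
    m = float((k * p).sum())
    v = float(((k - m) ** 2 * p).sum())
    return m, v


@pytest.fixture(scope="module")
def drink_samples():
    cfg = SimulationConfig()
    rng = kind_rng(0, 0, "drink")
    return [sample_drink_events(cfg, rng) for _ in range(N_SCHEDULES)]


def test_drink_counts_and_sizes_respect_bounds(drink_samples, config):
    for events in drink_samples:
        assert config.drink_bouts_min <= len(events) <= config.drink_bouts_max
        for ev in events:
            assert config.drink_size_min <= ev.magnitude <= config.drink_size_max
            assert ev.kind == "drink"
        assert all(a.time <= b.time for a, b in zip(events, events[1:]))


def test_drink_count_mean_matches_truncated_poisson(drink_samples, config):
    m, v = truncated_poisson_moments(
        config.drink_bouts_mean, config.drink_bouts_min, config.drink_bouts_max
    )
    counts = np.array([len(e) for e in drink_samples])
    se = np.sqrt(v / len(counts))
    assert abs(counts.mean() - m) < 3 * se


def test_drink_count_distribution_chi_square(drink_samples, config):
    """Empirical bout counts fit the truncated-Poisson pmf (α = 0.01)."""
    lo, hi = config.drink_bouts_min, config.drink_bouts_max
    k = np.arange(lo, hi + 1)
    pmf = stats.poisson.pmf(k, config.drink_bouts_mean)
    pmf = pmf / pmf.sum()
    observed = np.bincount(
        [len(e) for e in drink_samples], minlength=hi + 1
    )[lo:hi + 1]
    _, p = stats.chisquare(observed, pmf * N_SCHEDULES)
    assert p > 0.01


def test_degenerate_truncation_gives_fixed_count(config):
    cfg = config.replace(drink_bouts_min=8, drink_bouts_max=8)
    rng = kind_rng(1, 0, "drink")
    assert all(len(sample_drink_events(cfg, rng)) == 8 for _ in range(50))


def test_infeasible_truncation_raises(config):
    # distribution mass essentially never lands in the bounds
    cfg = config.replace(drink_bouts_mean=0.001, drink_bouts_min=14,
                         drink_bouts_max=15)
    with pytest.raises(ValueError, match="rejected"):
        sample_drink_events(cfg, kind_rng(0, 0, "drink"))


# ---------------------------------------------------------------------------
# circadian time mixture
# ---------------------------------------------------------------------------

def test_event_times_all_daytime_when_prob_one(config, rng):
    cfg = config.replace(daytime_event_prob=1.0)
    t = sample_event_times(cfg, rng, 10_000)
    assert np.all((t >= 360) & (t < 1320))


def test_event_times_on_grid_and_in_horizon(config, rng):
    cfg = config.replace(time_step=5)
    t = sample_event_times(cfg, rng, 10_000)
    assert np.all((t >= 0) & (t < cfg.horizon))
    assert np.all(t % cfg.time_step == 0)


def test_daytime_fraction_matches_mixture_probability(config, rng):
    n = 100_000
    t = sample_event_times(config, rng, n)
    frac = np.mean((t >= config.daytime_start) & (t < config.daytime_end))
    p = config.daytime_event_prob
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


# ---------------------------------------------------------------------------
# meals
# ---------------------------------------------------------------------------

def test_meal_magnitudes_sum_to_daily_total(config):
    rng = kind_rng(0, 0, "meal")
    for _ in range(2000):
        meals = sample_meal_events(config, rng)
        total = sum(ev.magnitude for ev in meals)
        assert config.meals_min <= len(meals) <= config.meals_max
        assert config.feed_total_min - 1e-9 <= total <= config.feed_total_max + 1e-9


def test_single_meal_gets_entire_total(config):
    cfg = config.replace(meals_min=1, meals_max=1)
    rng = kind_rng(3, 0, "meal")
    meals = sample_meal_events(cfg, rng)
    assert len(meals) == 1
    assert cfg.feed_total_min <= meals[0].magnitude <= cfg.feed_total_max


def test_mean_daily_feed_total_matches_uniform_mean(config):
    rng = kind_rng(7, 0, "meal")
    totals = np.array([
        sum(ev.magnitude for ev in sample_meal_events(config, rng))
        for _ in range(N_SCHEDULES)
    ])
    # uniform(2.5, 3.0): mean 2.75, var (0.5^2)/12
    se = np.sqrt(0.5**2 / 12 / N_SCHEDULES)
    assert abs(totals.mean() - 2.75) < 3 * se


# ---------------------------------------------------------------------------
# eliminations
# ---------------------------------------------------------------------------

def test_elimination_counts_in_bounds_and_targets_sum(config):
    u_rng = kind_rng(0, 0, "urination")
    f_rng = kind_rng(0, 0, "defecation")
    for _ in range(2000):
        urinations, defecations = sample_elimination_events(config, u_rng, f_rng)
        assert 6 <= len(urinations) <= 10
        assert 2 <= len(defecations) <= 4
        assert sum(e.magnitude for e in urinations) == pytest.approx(
            config.urine_daily_total)
        assert sum(e.magnitude for e in defecations) == pytest.approx(
            config.feces_daily_total)


def test_degenerate_urination_range(config):
    cfg = config.replace(urinations_min=6, urinations_max=6)
    u, _ = sample_elimination_events(
        cfg, kind_rng(2, 0, "urination"), kind_rng(2, 0, "defecation"))
    assert len(u) == 6


def test_mean_urination_count_matches_discrete_uniform(config):
    rng_u = kind_rng(11, 0, "urination")
    rng_f = kind_rng(11, 0, "defecation")
    counts = np.array([
        len(sample_elimination_events(config, rng_u, rng_f)[0])
        for _ in range(N_SCHEDULES)
    ])
    # uniform{6..10}: mean 8, var ((10-6+1)^2 - 1)/12 = 2
    se = np.sqrt(2.0 / N_SCHEDULES)
    assert abs(counts.mean() - 8.0) < 3 * se


# ---------------------------------------------------------------------------
# determinism and substream isolation
# ---------------------------------------------------------------------------

def test_same_seed_gives_identical_schedule_and_serialization(config):
    a = sample_schedule(config, pig_id=5)
    b = sample_schedule(config, pig_id=5)
    assert a == b
    assert a.to_frame().to_csv(index=False) == b.to_frame().to_csv(index=False)


def test_adding_pigs_never_perturbs_earlier_pigs(config):
    first = [sample_schedule(config, i) for i in range(3)]
    again = [sample_schedule(config, i) for i in range(10)][:3]
    assert first == again


def test_schedules_differ_across_pigs_and_seeds(config):
    assert sample_schedule(config, 0) != sample_schedule(config, 1)
    assert sample_schedule(config, 0) != sample_schedule(
        config.replace(seed=1), 0)
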