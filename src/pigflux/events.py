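"""Stochastic daily event schedules: drinking, feeding, urination, defecation.

Each simulated pig-day is driven by four independent streams of discrete
events.  Drinking-bout counts follow a truncated Poisson law and bout sizes
a truncated gamma law; daily feed is split over a handful of meals by a
symmetric Dirichlet; elimination events carry Dirichlet-allocated target
masses against a continuously filling reservoir.  Event times follow a
two-level circadian mixture: uniform within the daytime activity window
with high probability, uniform over the night otherwise.

Randomness is organised as deterministic substreams keyed by
``(seed, pig_id, event kind)`` so that simulating additional pigs, or
perturbing parameters of one event kind, never disturbs the draws of any
other pig or kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "Event",
    "EventSchedule",
    "kind_rng",
    "sample_event_time",
    "sample_event_times",
    "sample_drink_events",
    "sample_meal_events",
    "sample_elimination_events",
    "sample_schedule",
]

#: Number of attempts allowed when rejection-sampling a truncated law.
REJECTION_CAP = 10_000

_KIND_CODES = {"drink": 0, "meal": 1, "urination": 2, "defecation": 3}


class InfeasibleConfigError(ValueError):
    """Truncation bounds capture essentially no probability mass."""


@dataclass(frozen=True)
class Event:
    """One discrete event on the simulation grid.

    ``magnitude`` is the mass added (drinks: water; meals: feed before
    water binding) or, for eliminations, the *target* mass to remove —
    the realised removal is capped by reservoir content downstream.
    """

    time: int          # minute-of-day on the grid, in [0, horizon)
    magnitude: float   # kg, > 0
    kind: str          # drink | meal | urination | defecation

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("event magnitude must be positive")


@dataclass(frozen=True)
class EventSchedule:
    """Time-ordered events of one pig-day, grouped by kind."""

    drinks: tuple[Event, ...]
    meals: tuple[Event, ...]
    urinations: tuple[Event, ...]
    defecations: tuple[Event, ...]
    pig_id: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns pig_id, kind, time_min, magnitude_kg."""
        rows = [
            (self.pig_id, ev.kind, ev.time, ev.magnitude)
            for group in (self.drinks, self.meals,
                          self.urinations, self.defecations)
            for ev in group
        ]
        return pd.DataFrame(
            rows, columns=["pig_id", "kind", "time_min", "magnitude_kg"]
        )


# ---------------------------------------------------------------------------
# RNG substreams
# ---------------------------------------------------------------------------

def kind_rng(seed: int, pig_id: int, kind: str) -> np.random.Generator:
    """Deterministic generator for one (pig, event-kind) substream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(pig_id), _KIND_CODES[kind]])
    )


# ---------------------------------------------------------------------------
# Event-time sampling (circadian mixture)
# ---------------------------------------------------------------------------

def _grid_minutes(config: SimulationConfig) -> np.ndarray:
    return np.arange(0, config.horizon, config.time_step)


def sample_event_times(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` event minutes from the day/night mixture.

    With probability ``daytime_event_prob`` a minute is uniform on the
    daytime grid [daytime_start, daytime_end); otherwise uniform on the
    complementary night grid.  If the night window is empty every draw
    falls in daytime.
    """
    grid = _grid_minutes(config)
    day_mask = (grid >= config.daytime_start) & (grid < config.daytime_end)
    day, night = grid[day_mask], grid[~day_mask]
    if day.size == 0:
        raise ValueError("daytime window contains no grid minutes")
    in_day = rng.random(n) < config.daytime_event_prob
    if night.size == 0:
        in_day[:] = True
    times = np.empty(n, dtype=np.int64)
    # draw both branches from the same stream in a fixed order for determinism
    for mask, pool in ((in_day, day), (~in_day, night)):
        k = int(mask.sum())
        if k:
            times[mask] = pool[rng.integers(0, pool.size, size=k)]
    return times


def sample_event_time(
    config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Single draw from the circadian time mixture."""
    return int(sample_event_times(config, rng, 1)[0])


# ---------------------------------------------------------------------------
# Truncated-law rejection helpers
# ---------------------------------------------------------------------------

def _truncated_poisson(
    rng: np.random.Generator, mean: float, lo: int, hi: int
) -> int:
    for _ in range(REJECTION_CAP):
        k = int(rng.poisson(mean))
        if lo <= k <= hi:
            return k
    raise InfeasibleConfigError(
        f"Poisson(mean={mean}) rejected {REJECTION_CAP} times for "
        f"bounds [{lo}, {hi}]"
    )


def _truncated_gamma(
    rng: np.random.Generator, shape: float, scale: float,
    lo: float, hi: float,
) -> float:
    for _ in range(REJECTION_CAP):
        x = float(rng.gamma(shape, scale))
        if lo <= x <= hi:
            return x
    raise InfeasibleConfigError(
        f"Gamma(shape={shape}, scale={scale}) rejected {REJECTION_CAP} "
        f"times for bounds [{lo}, {hi}]"
    )


# ---------------------------------------------------------------------------
# Per-kind samplers
# ---------------------------------------------------------------------------

def sample_drink_events(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Event, ...]:
    """Drinking bouts: truncated-Poisson count, truncated-gamma sizes."""
    n = _truncated_poisson(
        rng, config.drink_bouts_mean,
        config.drink_bouts_min, config.drink_bouts_max,
    )
    times = sample_event_times(config, rng, n)
    sizes = [
        _truncated_gamma(
            rng, config.drink_size_shape, config.drink_size_scale,
            config.drink_size_min, config.drink_size_max,
        )
        for _ in range(n)
    ]
    events = [Event(int(t), s, "drink") for t, s in zip(times, sizes)]
    return tuple(sorted(events, key=lambda e: e.time))


def sample_meal_events(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Event, ...]:
    """Meals: uniform daily total split by a symmetric Dirichlet.

    Magnitudes are feed mass only; the water-binding component is applied
    by the gastrointestinal kinetics.
    """
    total = float(rng.uniform(config.feed_total_min, config.feed_total_max))
    n = int(rng.integers(config.meals_min, config.meals_max + 1))
    if n == 0:
        return ()
    if n == 1:
        fracs = np.ones(1)
    else:
        fracs = rng.dirichlet(np.full(n, config.meal_dirichlet_alpha))
    times = sample_event_times(config, rng, n)
    events = [
        Event(int(t), float(f * total), "meal")
        for t, f in zip(times, fracs)
    ]
    return tuple(sorted(events, key=lambda e: e.time))


def _elimination_kind(
    config: SimulationConfig, rng: np.random.Generator,
    kind: str, lo: int, hi: int, daily_total: float,
) -> tuple[Event, ...]:
    n = int(rng.integers(lo, hi + 1))
    if n == 0:
        return ()
    if n == 1:
        shares = np.ones(1)
    else:
        shares = rng.dirichlet(np.full(n, config.elimination_dirichlet_alpha))
    times = sample_event_times(config, rng, n)
    events = [
        Event(int(t), float(s * daily_total), kind)
        for t, s in zip(times, shares)
    ]
    return tuple(sorted(events, key=lambda e: e.time))


def sample_elimination_events(
    config: SimulationConfig,
    urine_rng: np.random.Generator,
    feces_rng: np.random.Generator,
) -> tuple[tuple[Event, ...], tuple[Event, ...]]:
    """Urination and defecation events with Dirichlet-share target masses.

    Targets are shares of the kind's daily excretion total so the expected
    removals match the reservoir's accumulation; actual removed mass is
    resolved against reservoir content at trajectory time.
    """
    urinations = _elimination_kind(
        config, urine_rng, "urination",
        config.urinations_min, config.urinations_max,
        config.urine_daily_total,
    )
    defecations = _elimination_kind(
        config, feces_rng, "defecation",
        config.defecations_min, config.defecations_max,
        config.feces_daily_total,
    )
    return urinations, defecations


def sample_schedule(config: SimulationConfig, pig_id: int) -> EventSchedule:
    """Full event schedule for one pig-day from its per-kind substreams."""
    drinks = sample_drink_events(config, kind_rng(config.seed, pig_id, "drink"))
    meals = sample_meal_events(config, kind_rng(config.seed, pig_id, "meal"))
    urinations, defecations = sample_elimination_events(
        config,
        kind_rng(config.seed, pig_id, "urination"),
        kind_rng(config.seed, pig_id, "defecation"),
    )
    return EventSchedule(
        drinks=drinks, meals=meals,
        urinations=urinations, defecations=defecations,
        pig_id=pig_id,
    )
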