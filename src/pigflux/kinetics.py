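"""Minute-resolution mass-component trajectories.

Three kinetic primitives turn an event schedule into component mass series
on the simulation grid:

* **linear clearance** — each drinking bout adds its water mass
  instantaneously and sheds it linearly over a fixed clearance window
  (180 min by default);
* **linear gastrointestinal passage** — each meal adds feed mass plus a
  water-binding fraction and empties linearly over the transit time
  (12 h by default);
* **reservoir dynamics** — urine and feces accumulate at a constant rate
  matching the daily excretion total, with instantaneous removals at
  elimination events, each capped at current reservoir content.

All kinetics are evaluated in closed form at each grid point, so halving
the time step changes no value at shared grid points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .events import Event, EventSchedule

__all__ = [
    "ComponentTrajectories",
    "time_grid",
    "water_trajectory",
    "gi_trajectory",
    "reservoir_trajectory",
    "component_trajectories",
]


def time_grid(config: SimulationConfig) -> np.ndarray:
    """Grid minutes 0..horizon inclusive (``n_steps + 1`` points)."""
    return np.arange(0, config.horizon + config.time_step, config.time_step,
                     dtype=np.int64)


@dataclass(frozen=True)
class ComponentTrajectories:
    """The four transient mass components of one pig-day, on a shared grid."""

    time: np.ndarray    # minutes, 0..horizon inclusive
    water: np.ndarray   # kg, drinking-water clearance component
    gi: np.ndarray      # kg, gastrointestinal fill (feed + bound water)
    urine: np.ndarray   # kg, urine reservoir level
    feces: np.ndarray   # kg, fecal reservoir level

    def __post_init__(self) -> None:
        n = self.time.shape[0]
        for name in ("water", "gi", "urine", "feces"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"component {name!r} does not match the grid")

    def total(self) -> np.ndarray:
        return self.water + self.gi + self.urine + self.feces

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time,
            "water_kg": self.water,
            "gi_kg": self.gi,
            "urine_kg": self.urine,
            "feces_kg": self.feces,
        })


# ---------------------------------------------------------------------------
# Linear-decay components (superposition of per-event closed forms)
# ---------------------------------------------------------------------------

def _linear_decay_sum(
    events: Iterable[Event], grid: np.ndarray, window: float,
    gain: float = 1.0,
) -> np.ndarray:
    """Sum of per-event ramps ``m·gain·max(0, 1 − (t−t0)/window)`` for t ≥ t0."""
    out = np.zeros(grid.shape[0])
    t = grid.astype(np.float64)
    for ev in events:
        frac = 1.0 - (t - ev.time) / window
        contrib = ev.magnitude * gain * np.clip(frac, 0.0, 1.0)
        contrib[t < ev.time] = 0.0
        out += contrib
    return out


def water_trajectory(
    drinks: Sequence[Event], config: SimulationConfig
) -> np.ndarray:
    """Drinking-water mass: instantaneous jumps, linear clearance."""
    return _linear_decay_sum(
        drinks, time_grid(config), config.drink_clearance_window
    )


def gi_trajectory(
    meals: Sequence[Event], config: SimulationConfig
) -> np.ndarray:
    """Gastrointestinal fill: feed plus bound water, linear passage."""
    return _linear_decay_sum(
        meals, time_grid(config), config.gi_transit_time,
        gain=1.0 + config.water_binding_frac,
    )


# ---------------------------------------------------------------------------
# Reservoir component
# ---------------------------------------------------------------------------

def _steady_state_level(daily_total: float, n_events: int) -> float:
    # expected level midway between equally spaced eliminations
    if n_events == 0:
        return 0.0
    return 0.5 * daily_total / n_events


def reservoir_trajectory(
    events: Sequence[Event], daily_total: float, config: SimulationConfig,
    initial_level: float | None = None,
) -> np.ndarray:
    """Constant-rate accumulation with capped instantaneous removals.

    The series value AT an elimination minute is post-removal.  Removals
    are ``min(target, current level)`` so the level never goes negative.
    ``initial_level`` defaults to 0, or to half the mean inter-event
    content when ``reservoir_initial_steady_state`` is set.
    """
    grid = time_grid(config)
    if initial_level is None:
        initial_level = (
            _steady_state_level(daily_total, len(events))
            if config.reservoir_initial_steady_state else 0.0
        )
    rate = daily_total / config.horizon           # kg per minute
    level = initial_level + rate * grid.astype(np.float64)
    removed = 0.0
    for ev in sorted(events, key=lambda e: e.time):
        current = initial_level + rate * ev.time - removed
        removal = min(ev.magnitude, current)
        removed += removal
        level[grid >= ev.time] -= removal
    # exhaustive removals can leave −1e−16-scale float residue at event minutes
    np.maximum(level, 0.0, out=level)
    return level


def component_trajectories(
    schedule: EventSchedule, config: SimulationConfig
) -> ComponentTrajectories:
    """All four component series for one pig-day."""
    grid = time_grid(config)
    return ComponentTrajectories(
        time=grid,
        water=water_trajectory(schedule.drinks, config),
        gi=gi_trajectory(schedule.meals, config),
        urine=reservoir_trajectory(
            schedule.urinations, config.urine_daily_total, config
        ),
        feces=reservoir_trajectory(
            schedule.defecations, config.feces_daily_total, config
        ),
    )
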