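"""Simulation configuration for the diurnal live-weight model.

All tunable parameters of the simulator live in :class:`SimulationConfig`.
Physiological ranges (drinking-bout counts and sizes, daily feed totals,
meal counts, elimination-event counts, clearance and transit windows, the
daily growth target) default to values appropriate for a finishing pig of
roughly 100 kg live weight.  Parameters the physiology does not pin down
(gamma bout-size shape/scale, circadian day-time probability, Dirichlet
concentration, daily excretion totals) carry calibrated defaults documented
in ``docs/methods.md`` and are fully overridable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["SimulationConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameter set for one simulation run.

    Instances are immutable; derive perturbed configurations with
    :meth:`replace`.  Validation runs on construction and raises
    ``ValueError`` naming the offending field.
    """

    # --- temporal resolution ------------------------------------------------
    time_step: int = 1          # minutes per grid step
    horizon: int = 1440         # minutes simulated (24 h)

    # --- baseline animal ----------------------------------------------------
    baseline_mass_W0: float = 100.0   # kg
    daily_gain: float = 0.8           # kg net growth over the 24 h horizon

    # --- drinking behaviour -------------------------------------------------
    drink_bouts_mean: float = 11.0    # Poisson mean, truncated to the bounds
    drink_bouts_min: int = 8
    drink_bouts_max: int = 15
    drink_size_min: float = 0.4       # kg per bout
    drink_size_max: float = 1.6
    drink_size_shape: float = 6.0     # gamma shape (unitless)
    drink_size_scale: float = 0.15    # gamma scale (kg)
    drink_clearance_window: float = 180.0   # minutes of linear clearance

    # --- circadian event timing ---------------------------------------------
    daytime_start: int = 360          # 06:00 in minutes-of-day
    daytime_end: int = 1320           # 22:00
    daytime_event_prob: float = 0.85  # probability an event falls in daytime

    # --- feeding and gastrointestinal fill ----------------------------------
    feed_total_min: float = 2.5       # kg feed per day
    feed_total_max: float = 3.0
    meals_min: int = 3
    meals_max: int = 6
    meal_dirichlet_alpha: float = 4.0  # symmetric concentration for meal split
    water_binding_frac: float = 0.15   # extra water mass per kg feed
    gi_transit_time: float = 720.0     # minutes of linear passage (12 h)

    # --- elimination reservoirs ---------------------------------------------
    urinations_min: int = 6
    urinations_max: int = 10
    defecations_min: int = 2
    defecations_max: int = 4
    urine_daily_total: float = 4.0     # kg accumulated per day
    feces_daily_total: float = 1.5
    elimination_dirichlet_alpha: float = 4.0  # per-event target allocation
    reservoir_initial_steady_state: bool = False  # start reservoirs part-full

    # --- population / reproducibility ---------------------------------------
    n_pigs: int = 1000
    seed: int = 0
    exceedance_reference: str = "daily_mean"  # or "growth_line"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on the first violated invariant."""
        positive = [
            "time_step", "horizon", "baseline_mass_W0",
            "drink_bouts_mean", "drink_size_min", "drink_size_max",
            "drink_size_shape", "drink_size_scale", "drink_clearance_window",
            "feed_total_min", "feed_total_max", "meal_dirichlet_alpha",
            "gi_transit_time", "urine_daily_total", "feces_daily_total",
            "elimination_dirichlet_alpha",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.horizon % self.time_step != 0:
            raise ValueError("horizon must be divisible by time_step")
        ordered = [
            ("drink_bouts_min", "drink_bouts_max"),
            ("drink_size_min", "drink_size_max"),
            ("feed_total_min", "feed_total_max"),
            ("meals_min", "meals_max"),
            ("urinations_min", "urinations_max"),
            ("defecations_min", "defecations_max"),
        ]
        for lo, hi in ordered:
            if getattr(self, lo) > getattr(self, hi):
                raise ValueError(f"{lo} must not exceed {hi}")
        counts = [
            "drink_bouts_min", "meals_min", "urinations_min",
            "defecations_min",
        ]
        for name in counts:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.daytime_event_prob <= 1):
            raise ValueError("daytime_event_prob must be in (0, 1]")
        if not (0 <= self.water_binding_frac < 1):
            raise ValueError("water_binding_frac must be in [0, 1)")
        if not (0 <= self.daytime_start < self.daytime_end <= self.horizon):
            raise ValueError(
                "daytime_start/daytime_end must satisfy "
                "0 <= start < end <= horizon"
            )
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be at least 1")
        if self.exceedance_reference not in ("daily_mean", "growth_line"):
            raise ValueError(
                "exceedance_reference must be 'daily_mean' or 'growth_line'"
            )

    # ------------------------------------------------------------------
    @property
    def n_steps(self) -> int:
        """Number of grid intervals; the grid has ``n_steps + 1`` points."""
        return self.horizon // self.time_step

    def replace(self, **changes: Any) -> "SimulationConfig":
        """Return a validated copy with ``changes`` applied."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        """Build from a mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**dict(data))
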