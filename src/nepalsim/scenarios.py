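"""Stressor scenarios: earthquake, fertility rate, and crop-yield variability.

A run combines one pathway from each of the three stressor dimensions:

* earthquake on/off (the composite 2015-event timeline versus a
  counterfactual in which it never happens),
* mean lifetime fertility of 1.6 or 2.1 children per woman,
* status-quo or heightened inter-annual crop-yield variability
  (half-yield recurrence intervals of 12/10 versus 9/7 years for
  subsistence/cash crops).

That yields eight scenario combinations, each encoded into the run's output
filename (e.g. ``EQ-21-12-01.csv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Mapping

from .clock import day_index_of

FERTILITY_SCENARIOS = (1.6, 2.1)
# (subsistence, cash) half-yield recurrence intervals in years.
CROP_VARIABILITY = {"status_quo": (12, 10), "heightened": (9, 7)}


@dataclass(frozen=True)
class ScenarioSettings:
    earthquake: bool = False
    fertility_rate: float = 2.1
    crop_variability: str = "status_quo"

    def __post_init__(self) -> None:
        if self.fertility_rate not in FERTILITY_SCENARIOS:
            raise ValueError(f"fertility_rate must be one of {FERTILITY_SCENARIOS}")
        if self.crop_variability not in CROP_VARIABILITY:
            raise ValueError(f"crop_variability must be one of {tuple(CROP_VARIABILITY)}")

    @property
    def half_yield_intervals(self) -> tuple[int, int]:
        """(subsistence, cash) recurrence intervals in years."""
        return CROP_VARIABILITY[self.crop_variability]

    def to_dict(self) -> dict[str, Any]:
        return {
            "earthquake": self.earthquake,
            "fertility_rate": self.fertility_rate,
            "crop_variability": self.crop_variability,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioSettings":
        return cls(
            earthquake=bool(d.get("earthquake", False)),
            fertility_rate=float(d.get("fertility_rate", 2.1)),
            crop_variability=str(d.get("crop_variability", "status_quo")),
        )


def all_scenario_combinations() -> list[ScenarioSettings]:
    """The eight stressor-pathway combinations, in a stable order."""
    combos = []
    for eq in (True, False):
        for fert in (2.1, 1.6):
            for cv in ("status_quo", "heightened"):
                combos.append(ScenarioSettings(eq, fert, cv))
    return combos


# --------------------------------------------------------------------------
# Run-file naming
# --------------------------------------------------------------------------

_NAME_RE = re.compile(r"^(EQ|NE)-(16|21)-(12|09)-(\d+)\.csv$")


def encode_run_name(settings: ScenarioSettings, seed: int) -> str:
    """``{EQ|NE}-{16|21}-{12|09}-{seed}.csv`` — e.g. ``EQ-21-12-01.csv``.

    ``NE`` (no earthquake) is this artifact's code for the counterfactual
    pathway.  The seed is zero-padded to at least two digits.
    """
    eq = "EQ" if settings.earthquake else "NE"
    fert = "21" if settings.fertility_rate == 2.1 else "16"
    cv = "12" if settings.crop_variability == "status_quo" else "09"
    return f"{eq}-{fert}-{cv}-{seed:02d}.csv"


def decode_run_name(name: str) -> tuple[ScenarioSettings, int]:
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a run filename: {name!r}")
    eq, fert, cv, seed = m.groups()
    return (
        ScenarioSettings(
            earthquake=eq == "EQ",
            fertility_rate=2.1 if fert == "21" else 1.6,
            crop_variability="status_quo" if cv == "12" else "heightened",
        ),
        int(seed),
    )


# --------------------------------------------------------------------------
# Earthquake timeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EarthquakeTimeline:
    """Dates and magnitudes of the composite 2015-earthquake event.

    All effects fire at most once.  Day indices are on the model's no-leap
    calendar (0 = 1 Jan 2015).
    """

    shock_day: int = day_index_of(2015, 4, 25)            # main shock
    yield_window_end: int = day_index_of(2015, 6, 12)     # one month after 7.3 Mw aftershock
    labour_stop_days: int = 91                            # three months of no labouring
    labour_boom_days: int = 730                           # then 24 months at 1.5x
    labour_boom_factor: float = 1.5
    loan_day: int = day_index_of(2016, 10, 25)            # reconstruction loans issued
    # household size -> loan (NPR); thresholds are inclusive lower bounds
    loan_schedule: tuple[tuple[int, float], ...] = ((7, 675000.0), (5, 550000.0),
                                                    (3, 425000.0), (1, 300000.0))
    livestock_mortality: float = 0.05
    emigration_probability: float = 0.5
    cash_crop_yield_factor: float = 0.85                  # permanent, from the shock onward
    in_window_yield_factor: float = 0.70                  # crops in the ground during the window

    def reconstruction_loan(self, household_size: int) -> float:
        for threshold, amount in self.loan_schedule:
            if household_size >= threshold:
                return amount
        return 0.0

    def labour_factor(self, day_index: int) -> float:
        """Multiplier on the daily labouring-opportunity probability."""
        if day_index < self.shock_day:
            return 1.0
        if day_index < self.shock_day + self.labour_stop_days:
            return 0.0
        if day_index < self.shock_day + self.labour_stop_days + self.labour_boom_days:
            return self.labour_boom_factor
        return 1.0

    def yield_hit_applies(self, plant_index: int, harvest_index: int) -> bool:
        """Whether a planting was in the ground during the damage window."""
        return plant_index <= self.yield_window_end and harvest_index >= self.shock_day
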