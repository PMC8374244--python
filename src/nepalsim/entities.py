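"""Agent state containers: villagers, households, animals, and the village.

These are deliberately plain mutable records.  All behaviour lives in the
process modules (demography, livestock, agriculture, finance); the engine
owns the daily schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .clock import DAYS_PER_YEAR, SimulationClock
from .ledger import Account, Ledger
from .params import ParameterSet
from .rng import RngStreams
from .scenarios import ScenarioSettings

ADULT_AGE_DAYS = 18 * DAYS_PER_YEAR


@dataclass
class Villager:
    id: int
    sex: str                      # "m" | "f"
    age_days: int
    household_id: int
    mother_id: Optional[int] = None
    father_id: Optional[int] = None
    partner_id: Optional[int] = None
    children_ids: list[int] = field(default_factory=list)
    education: str = "pre-school"     # pre-school | school | plus2 | left
    attainment: str = "none"          # none | SLC | plus2
    career: str = "child"             # child | student | farm | labourer |
                                      # salaried-1..4 | salaried-abroad | pensioner
    controller_id: Optional[str] = None   # account id
    marriage_age_days: Optional[int] = None
    death_age_days: int = 0
    married: bool = False
    widowed: bool = False
    desired_children: Optional[int] = None   # married women under 50 only
    next_birth_day: Optional[int] = None     # absolute day index
    marriage_day: Optional[int] = None       # absolute day index when married
    last_birth_day: Optional[int] = None
    abroad: bool = False
    alive: bool = True
    worked_today: bool = False

    @property
    def age_years(self) -> float:
        return self.age_days / DAYS_PER_YEAR

    @property
    def is_adult(self) -> bool:
        return self.age_days > ADULT_AGE_DAYS

    @property
    def in_education(self) -> bool:
        return self.education in ("pre-school", "school", "plus2")


@dataclass
class Animal:
    id: int
    species: str                  # chicken | goat | cattle | buffalo
    sex: str                      # "m" | "f"
    age_days: int
    household_id: int
    laying_cycle_day: int = -1    # chickens: days into the current lay/rest cycle
    births_done: int = 0          # index into the species birth schedule

    @property
    def is_bovine(self) -> bool:
        return self.species in ("cattle", "buffalo")


@dataclass
class Planting:
    crop: str
    n_fields: int
    plant_index: int
    harvest_index: int
    paddy: bool = False


@dataclass
class Household:
    id: int
    archetype: str
    member_ids: list[int] = field(default_factory=list)
    referent_id: Optional[int] = None
    total_fields: int = 0          # each field = 0.5 ropani
    paddy_fields: int = 0
    polytunnels: int = 0
    plantings: list[Planting] = field(default_factory=list)
    crop_strategy: dict[str, int] = field(default_factory=dict)
    remittance: bool = False
    account: Account = None  # type: ignore[assignment]
    # household-fission entitlement still owed to a fissioned-off son
    pending_field_claims: dict[int, int] = field(default_factory=dict)

    @property
    def ropani(self) -> float:
        return self.total_fields * 0.5

    @property
    def regular_fields(self) -> int:
        return self.total_fields - self.paddy_fields

    def fields_in_use(self) -> int:
        return sum(pl.n_fields for pl in self.plantings)

    def paddy_in_use(self) -> int:
        return sum(pl.n_fields for pl in self.plantings if pl.paddy)

    def unused_fields(self) -> int:
        return self.total_fields - self.fields_in_use()

    def unused_regular_fields(self) -> int:
        return self.regular_fields - (self.fields_in_use() - self.paddy_in_use())


@dataclass
class VillageState:
    """The whole simulated world at an instant."""

    clock: SimulationClock
    params: ParameterSet
    scenario: ScenarioSettings
    rng: RngStreams
    villagers: dict[int, Villager] = field(default_factory=dict)
    households: dict[int, Household] = field(default_factory=dict)
    animals: dict[int, Animal] = field(default_factory=dict)
    accounts: dict[str, Account] = field(default_factory=dict)
    ledger: Ledger = field(default_factory=Ledger)
    events: list[tuple[int, str, str]] = field(default_factory=list)
    # yield multipliers: {(sim_year, crop): multiplier}; sim_year may be
    # negative (the ten generated years of history, -10..-1)
    yield_multipliers: dict[tuple[int, str], float] = field(default_factory=dict)
    distributions: object = None          # ScheduleDistributions
    yield_models: dict = field(default_factory=dict)
    earthquake_timeline: object = None    # EarthquakeTimeline when active
    # population bookkeeping counters
    births: int = 0
    deaths: int = 0
    departures: int = 0
    arrivals: int = 0                     # in-marrying wives
    _next_villager_id: int = 0
    _next_animal_id: int = 0
    _next_household_id: int = 0

    # -- id factories -------------------------------------------------------

    def new_villager_id(self) -> int:
        vid = self._next_villager_id
        self._next_villager_id += 1
        return vid

    def new_animal_id(self) -> int:
        aid = self._next_animal_id
        self._next_animal_id += 1
        return aid

    def new_household_id(self) -> int:
        hid = self._next_household_id
        self._next_household_id += 1
        return hid

    # -- lookups ------------------------------------------------------------

    def household_members(self, h: Household) -> list[Villager]:
        return [self.villagers[i] for i in h.member_ids]

    def household_animals(self, h: Household) -> list[Animal]:
        return [a for a in self.animals.values() if a.household_id == h.id]

    def resident_members(self, h: Household) -> list[Villager]:
        """Members physically in the village (not working abroad)."""
        return [v for v in self.household_members(h) if not v.abroad]

    def adults(self, h: Household) -> list[Villager]:
        return [v for v in self.household_members(h) if v.is_adult]

    def account_of(self, v: Villager) -> Account:
        return self.accounts[v.controller_id]

    def log_event(self, kind: str, detail: str) -> None:
        self.events.append((self.clock.day_index, kind, detail))

    def population_identity_holds(self) -> bool:
        """births + arrivals - deaths - departures == net villager change."""
        # villagers dict holds only live residents; initial count recorded
        # by the engine as _initial_population.
        net = len(self.villagers) - getattr(self, "_initial_population", len(self.villagers))
        return net == self.births + self.arrivals - self.deaths - self.departures
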