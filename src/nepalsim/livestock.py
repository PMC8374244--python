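"""Animal dynamics: feed, eggs, milk, births, slaughter-and-replace cycles,
and the adult-count-driven ownership targets with bovine land caps.

Newborn animals are sold immediately and exiting animals are replaced by
purchased juveniles, so herds are demographically static between the
rebalancing trades.  Resale values interpolate linearly in age between the
purchase point and the slaughter point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entities import Animal, Household, VillageState
from .params import ParameterSet

SPECIES = ("chicken", "goat", "cattle", "buffalo")

# Stepped ownership targets by household adult count (a fixture standing in
# for the surveyed step functions; passes through the origin and increases
# with adult count).  Index = adult count, last entry applies beyond.
OWNERSHIP_STEPS = {
    "chicken": (0, 2, 3, 4, 5, 6),
    "goat": (0, 1, 2, 2, 3, 3),
    "bovine": (0, 1, 2, 2, 3, 3),
}

# Bovine caps by land holding (ropani): (inclusive upper bound, cap).
BOVINE_LAND_CAPS = ((5.4999, 0), (10.5, 1), (16.0, 2), (21.5, 3))
BOVINE_CAP_BEYOND = 4

GOAT_LITTER_SIZES = (1, 2, 3)
_RAW_LITTER = np.array([0.622, 0.333, 0.044])
GOAT_LITTER_PMF = _RAW_LITTER / _RAW_LITTER.sum()  # printed shares sum to 0.999

COW_BIRTH_AGES = (913, 1461, 2009, 2557, 3105, 3653, 4201)
BUFFALO_BIRTH_AGES = (1642, 2220, 2798, 3376)
GOAT_BIRTH_AGES = (329, 612)

LAYING_START_AGE = 183
LAYING_ON_DAYS = 30
LAYING_OFF_DAYS = 91  # three months
COW_MILK_CUTOFF_AGE = 4688
COW_MILK_BLACKOUT = 61   # two months before the next birth
BUFFALO_MILK_BLACKOUT = 91  # three months


@dataclass(frozen=True)
class SpeciesParams:
    species: str
    feed_kg: tuple[float, float, float]  # maize, millet, wheat per day
    purchase_age: int
    purchase_price: float
    exit_age_m: int
    exit_age_f: int
    exit_price_m: float
    exit_price_f: float
    replacement_age: int
    replacement_price: float

    def exit_age(self, sex: str) -> int:
        return self.exit_age_m if sex == "m" else self.exit_age_f

    def exit_price(self, sex: str) -> float:
        return self.exit_price_m if sex == "m" else self.exit_price_f


def species_table(p: ParameterSet) -> dict[str, SpeciesParams]:
    return {
        "chicken": SpeciesParams(
            "chicken", (0.032, 0.032, 0.010), 14, p.chicken_purchase_price,
            183, 1825, p.chicken_slaughter_price, p.chicken_slaughter_price,
            14, p.chicken_purchase_price),
        "goat": SpeciesParams(
            "goat", (0.025, 0.025, 0.0), 112, p.goat_purchase_price,
            730, 730, p.goat_slaughter_price, p.goat_slaughter_price,
            112, p.goat_purchase_price),
        # cattle die at 18 and are replaced; no carcass sale, so their resale
        # value holds at the purchase price
        "cattle": SpeciesParams(
            "cattle", (0.240, 0.240, 0.0), 548, p.cattle_purchase_price,
            18 * 365, 18 * 365, 0.0, 0.0, 548, p.cattle_purchase_price),
        "buffalo": SpeciesParams(
            "buffalo", (0.280, 0.280, 0.0), 548, p.buffalo_purchase_price,
            14 * 365, 10 * 365, p.male_buffalo_slaughter_price,
            p.female_buffalo_slaughter_price, 548, p.buffalo_purchase_price),
    }


def daily_feed_cost(sp: SpeciesParams, p: ParameterSet) -> float:
    m, mi, w = sp.feed_kg
    return m * p.maize_price + mi * p.millet_price + w * p.wheat_price


def draw_goat_litter(rng: np.random.Generator) -> int:
    return int(rng.choice(GOAT_LITTER_SIZES, p=GOAT_LITTER_PMF))


def _hen_is_laying(age_days: int) -> bool:
    if age_days < LAYING_START_AGE:
        return False
    return (age_days - LAYING_START_AGE) % (LAYING_ON_DAYS + LAYING_OFF_DAYS) \
        < LAYING_ON_DAYS


def _next_birth_age(age: int, schedule: tuple[int, ...]) -> int | None:
    for b in schedule:
        if b > age:
            return b
    return None


def step_animal(a: Animal, state: VillageState) -> None:
    """One day for one animal: ageing, feed, production, exit/replacement."""
    h = state.households.get(a.household_id)
    if h is None:
        raise RuntimeError(f"animal {a.id} has no owning household")
    p = state.params
    sp = species_table(p)[a.species]
    rng = state.rng.livestock
    day = state.clock.day_index
    acc = h.account
    ledger = state.ledger

    a.age_days += 1
    ledger.post(day, acc, "animal feed", -daily_feed_cost(sp, p))

    hh_size = len(h.member_ids)
    if a.species == "chicken" and a.sex == "f" and _hen_is_laying(a.age_days):
        ledger.post(day, acc, "eggs", p.egg_sale_price)
    elif a.species == "goat" and a.sex == "f" and a.age_days in GOAT_BIRTH_AGES:
        kids = draw_goat_litter(rng)
        ledger.post(day, acc, "animal trade", kids * p.goat_purchase_price)
    elif a.species == "cattle" and a.sex == "f":
        if a.age_days in COW_BIRTH_AGES:
            ledger.post(day, acc, "animal trade", p.cattle_purchase_price)
        if COW_BIRTH_AGES[0] < a.age_days < COW_MILK_CUTOFF_AGE and hh_size in (1, 2):
            nb = _next_birth_age(a.age_days, COW_BIRTH_AGES)
            if nb is None or nb - a.age_days > COW_MILK_BLACKOUT:
                rate = p.cow_milk_income_size1 if hh_size == 1 else p.cow_milk_income_size2
                ledger.post(day, acc, "milk", rate)
    elif a.species == "buffalo" and a.sex == "f":
        if a.age_days in BUFFALO_BIRTH_AGES:
            ledger.post(day, acc, "animal trade", p.buffalo_purchase_price)
        if a.age_days > BUFFALO_BIRTH_AGES[0] and hh_size in (1, 2):
            nb = _next_birth_age(a.age_days, BUFFALO_BIRTH_AGES)
            if nb is None or nb - a.age_days > BUFFALO_MILK_BLACKOUT:
                rate = p.buffalo_milk_income_size1 if hh_size == 1 \
                    else p.buffalo_milk_income_size2
                ledger.post(day, acc, "milk", rate)

    if a.age_days >= sp.exit_age(a.sex):
        proceeds = sp.exit_price(a.sex)
        if proceeds:
            ledger.post(day, acc, "animal trade", proceeds)
        ledger.post(day, acc, "animal trade", -sp.replacement_price)
        a.age_days = sp.replacement_age
        if a.species in ("chicken", "goat"):
            a.sex = "m" if rng.uniform() < 0.5 else "f"


# --------------------------------------------------------------------------
# Ownership targets and rebalancing
# --------------------------------------------------------------------------

def _step(table: tuple[int, ...], adults: int) -> int:
    return table[min(adults, len(table) - 1)]


def bovine_cap(ropani: float) -> int:
    for upper, cap in BOVINE_LAND_CAPS:
        if ropani <= upper:
            return cap
    return BOVINE_CAP_BEYOND


def target_animal_counts(h: Household, state: VillageState) -> dict[str, int]:
    """Deterministic targets: stepped in adult count, bovines capped by the
    household's land (fodder constraint)."""
    adults = len(state.adults(h))
    return {
        "chicken": _step(OWNERSHIP_STEPS["chicken"], adults),
        "goat": _step(OWNERSHIP_STEPS["goat"], adults),
        "bovine": min(_step(OWNERSHIP_STEPS["bovine"], adults),
                      bovine_cap(h.ropani)),
    }


def animal_value(a: Animal, params: ParameterSet) -> float:
    """Linear interpolation of worth between purchase and slaughter age."""
    sp = species_table(params)[a.species]
    a0, p0 = sp.purchase_age, sp.purchase_price
    a1, p1 = sp.exit_age(a.sex), sp.exit_price(a.sex)
    if a.species == "cattle":
        p1 = sp.purchase_price  # no carcass market; value holds
    if a.age_days <= a0:
        return p0
    if a.age_days >= a1:
        return p1
    return p0 + (p1 - p0) * (a.age_days - a0) / (a1 - a0)


def _buy_animal(state: VillageState, h: Household, species: str, sex: str,
                age: int, price: float, charge: bool = True) -> Animal:
    a = Animal(id=state.new_animal_id(), species=species, sex=sex,
               age_days=age, household_id=h.id)
    state.animals[a.id] = a
    if charge:
        state.ledger.post(state.clock.day_index, h.account, "animal trade", -price)
    return a


def rebalance_animals(h: Household, state: VillageState) -> None:
    """Buy to cover deficits, sell youngest-first to shed surpluses."""
    p = state.params
    rng = state.rng.livestock
    targets = target_animal_counts(h, state)
    owned = state.household_animals(h)
    counts = {
        "chicken": sum(1 for a in owned if a.species == "chicken"),
        "goat": sum(1 for a in owned if a.species == "goat"),
        "bovine": sum(1 for a in owned if a.is_bovine),
    }
    for group in ("chicken", "goat"):
        sp = species_table(p)[group]
        for _ in range(max(0, targets[group] - counts[group])):
            sex = "m" if rng.uniform() < 0.5 else "f"
            _buy_animal(state, h, group, sex, sp.purchase_age, sp.purchase_price)
    for _ in range(max(0, targets["bovine"] - counts["bovine"])):
        species = "buffalo" if rng.uniform() < 0.4 else "cattle"
        has_breed = any(a.species == species for a in state.household_animals(h))
        sex = "m" if has_breed else "f"
        sp = species_table(p)[species]
        _buy_animal(state, h, species, sex, sp.purchase_age, sp.purchase_price)
    # surpluses: youngest first, at interpolated worth
    for group in ("chicken", "goat", "bovine"):
        surplus = counts[group] - targets[group]
        if surplus <= 0:
            continue
        members = sorted((a for a in state.household_animals(h)
                          if (a.is_bovine if group == "bovine"
                              else a.species == group)),
                         key=lambda a: (a.age_days, a.id))
        for a in members[:surplus]:
            state.ledger.post(state.clock.day_index, h.account, "animal trade",
                              animal_value(a, p))
            del state.animals[a.id]


def initialize_household_animals(state: VillageState, h: Household) -> None:
    """Starting herd at the ownership targets, with ages drawn uniformly
    over each species' viable range.  No money changes hands: the herd
    predates the simulated window."""
    p = state.params
    rng = state.rng.livestock
    targets = target_animal_counts(h, state)
    table = species_table(p)
    for group, n in (("chicken", targets["chicken"]), ("goat", targets["goat"])):
        sp = table[group]
        for _ in range(n):
            sex = "m" if rng.uniform() < 0.5 else "f"
            age = int(rng.integers(sp.purchase_age, sp.exit_age(sex)))
            _buy_animal(state, h, group, sex, age, 0.0, charge=False)
    for _ in range(targets["bovine"]):
        species = "buffalo" if rng.uniform() < 0.4 else "cattle"
        has_breed = any(a.species == species for a in state.household_animals(h))
        sex = "m" if has_breed else "f"
        sp = table[species]
        age = int(rng.integers(sp.purchase_age, sp.exit_age(sex)))
        _buy_animal(state, h, species, sex, age, 0.0, charge=False)
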