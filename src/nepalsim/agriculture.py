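"""Cropping: yield distributions, forecasts, strategy, planting, harvest,
and polytunnels.

Annual yields are modal-yield multipliers drawn from beta distributions
calibrated so that a half yield (multiplier <= 0.5) recurs once every T
years on average: T = 12/10 (subsistence/cash) under the status quo, 9/7
under heightened variability.  A household's crop strategy covers its
forecast grain needs first (exponential smoothing of the last ten years'
multipliers) and splits the remaining non-paddy fields between potato,
cabbage and cauliflower in the fixed 20:9:3 ratio; paddy fields always
carry rice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clock import DAYS_PER_YEAR
from .entities import Household, Planting, VillageState
from .params import (CASH_CROPS, FOOD_BASKET, GRAIN_CROPS, CropParams,
                     consumption_multiplier, crop_table)
from .livestock import species_table

CASH_CROP_RATIO = {"potato": 20, "cabbage": 9, "cauliflower": 3}
CASH_CROP_PRIORITY = ("potato", "cabbage", "cauliflower")

YIELD_SUPPORT_MAX = 1.25  # multiplier support [0, 1.25], mode pinned at 1.0


@dataclass(frozen=True)
class YieldDistribution:
    """Beta-family multiplier distribution with mode 1.0 and calibrated
    half-yield tail mass."""

    alpha: float
    beta: float
    support_max: float = YIELD_SUPPORT_MAX

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta) * self.support_max)

    def cdf(self, x: float) -> float:
        return float(stats.beta.cdf(x / self.support_max, self.alpha, self.beta))

    def mode(self) -> float:
        return (self.alpha - 1) / (self.alpha + self.beta - 2) * self.support_max


def calibrate_yield_distribution(half_yield_interval_years: float,
                                 support_max: float = YIELD_SUPPORT_MAX,
                                 tol: float = 1e-6) -> YieldDistribution:
    """Solve for the beta shape giving P(multiplier <= 0.5) = 1/T.

    The mode is pinned at 1.0 on [0, support_max], leaving one free
    concentration parameter k with alpha = 1 + m*k, beta = 1 + (1-m)*k,
    m = 1/support_max.  The tail mass is monotone decreasing in k, so
    bisection converges; an unreachable target raises.
    """
    T = half_yield_interval_years
    if T <= 1:
        raise ValueError("half-yield interval must exceed 1 year")
    m = 1.0 / support_max
    x = 0.5 / support_max
    target = 1.0 / T

    def tail(k: float) -> float:
        return float(stats.beta.cdf(x, 1 + m * k, 1 + (1 - m) * k))

    lo, hi = 1e-9, 1e4
    if not (tail(hi) <= target <= tail(lo)):
        raise ValueError(f"half-yield target 1/{T} not reachable on this support")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if tail(mid) > target:
            lo = mid
        else:
            hi = mid
    k = 0.5 * (lo + hi)
    return YieldDistribution(alpha=1 + m * k, beta=1 + (1 - m) * k,
                             support_max=support_max)


def build_yield_models(scenario) -> dict[str, YieldDistribution]:
    t_sub, t_cash = scenario.half_yield_intervals
    return {"subsistence": calibrate_yield_distribution(t_sub),
            "cash": calibrate_yield_distribution(t_cash)}


def generate_yield_series(state: VillageState) -> None:
    """Ten years of history plus the fifteen simulated years, per crop.
    Crops' multipliers are mutually independent within a year."""
    crops = crop_table(state.params)
    rng = state.rng.yields
    for year in range(-10, 15):
        for name, cp in crops.items():
            model = state.yield_models["cash" if cp.is_cash else "subsistence"]
            state.yield_multipliers[(year, name)] = model.sample(rng)


def forecast_yields(history: list[float], alpha: float) -> float:
    """Simple exponential smoothing over a (normally ten-year) window,
    most recent observation last and weighted highest."""
    if not history:
        raise ValueError("need at least one year of yield history")
    s = history[0]
    for y in history[1:]:
        s = alpha * y + (1 - alpha) * s
    return s


def forecast_multiplier(state: VillageState, crop: str) -> float:
    year = state.clock.sim_year
    history = [state.yield_multipliers[(y, crop)]
               for y in range(year - 10, year)
               if (y, crop) in state.yield_multipliers]
    return forecast_yields(history, state.params.yield_smoothing_alpha)


# --------------------------------------------------------------------------
# Crop strategy
# --------------------------------------------------------------------------

def allocate_cash_crop_fields(surplus_fields: int) -> dict[str, int]:
    """Split surplus fields 20:9:3 by largest remainder; ties and leftovers
    favour potato over cabbage over cauliflower.  Totals are preserved."""
    total_ratio = sum(CASH_CROP_RATIO.values())
    quotas = {c: surplus_fields * r / total_ratio for c, r in CASH_CROP_RATIO.items()}
    alloc = {c: math.floor(q) for c, q in quotas.items()}
    leftover = surplus_fields - sum(alloc.values())
    order = sorted(CASH_CROP_PRIORITY,
                   key=lambda c: (-(quotas[c] - alloc[c]), CASH_CROP_PRIORITY.index(c)))
    for c in order[:leftover]:
        alloc[c] += 1
    return alloc


def household_grain_need_kg(h: Household, state: VillageState) -> dict[str, float]:
    """Conservative 12-month grain requirement: current resident members
    (plus any birth already scheduled within the year) and the current
    herd's feed, in kg per grain."""
    need = {g: 0.0 for g in GRAIN_CROPS}
    horizon = state.clock.day_index + DAYS_PER_YEAR
    for v in state.resident_members(h):
        mult = consumption_multiplier(v.sex, v.age_years)
        for g in GRAIN_CROPS:
            need[g] += FOOD_BASKET[g][0] * mult * DAYS_PER_YEAR
        if v.next_birth_day is not None and v.next_birth_day <= horizon:
            infant_mult = consumption_multiplier("f", 0)
            for g in GRAIN_CROPS:
                need[g] += FOOD_BASKET[g][0] * infant_mult * DAYS_PER_YEAR
    table = species_table(state.params)
    for a in state.household_animals(h):
        feed = table[a.species].feed_kg
        for g, kg in zip(GRAIN_CROPS, feed):
            need[g] += kg * DAYS_PER_YEAR
    return need


def update_crop_strategy(h: Household, state: VillageState) -> dict[str, int]:
    """Grain minimums first, then the 20:9:3 cash-crop split; paddy fields
    are pinned to rice."""
    crops = crop_table(state.params)
    need = household_grain_need_kg(h, state)
    grain_fields: dict[str, int] = {}
    for g in GRAIN_CROPS:
        mult = max(forecast_multiplier(state, g), 1e-9)
        per_field_kg = mult * crops[g].standard_yield * 0.5
        grain_fields[g] = math.ceil(need[g] / per_field_kg)
    available = h.regular_fields
    total_grain = sum(grain_fields.values())
    if total_grain > available:
        # grain needs exceed the farm: everything to grain, proportionally
        state.log_event("grain-shortfall",
                        f"H{h.id} needs {total_grain} fields, has {available}")
        quotas = {g: available * grain_fields[g] / total_grain for g in GRAIN_CROPS}
        scaled = {g: math.floor(q) for g, q in quotas.items()}
        leftover = available - sum(scaled.values())
        for g in sorted(GRAIN_CROPS, key=lambda g: -(quotas[g] - scaled[g]))[:leftover]:
            scaled[g] += 1
        grain_fields = scaled
    surplus = available - sum(grain_fields.values())
    strategy = dict(grain_fields)
    strategy.update(allocate_cash_crop_fields(surplus))
    strategy["rice"] = h.paddy_fields
    h.crop_strategy = strategy
    return strategy


# --------------------------------------------------------------------------
# Planting and harvest
# --------------------------------------------------------------------------

def planting_cost_per_field(cp: CropParams, params) -> float:
    """Seed plus fertiliser/pesticide for one half-ropani field."""
    if cp.seed_flat_npr_per_ropani is not None:
        seed = cp.seed_flat_npr_per_ropani / 2.0
    else:
        seed = cp.seed_kg_per_ropani * cp.price / 2.0
    return seed + cp.fertiliser_npr_per_ropani / 2.0


def _has_plough_animal(h: Household, state: VillageState) -> bool:
    return any(a.is_bovine and a.sex == "m"
               for a in state.household_animals(h))


def plant_crop(h: Household, crop: str, state: VillageState,
               n_override: int | None = None, charge: bool = True) -> Planting | None:
    """Plant today's crop per the current strategy, within unused fields."""
    cp = crop_table(state.params)[crop]
    intended = n_override if n_override is not None \
        else h.crop_strategy.get(crop, 0)
    if crop == "rice":
        capacity = h.paddy_fields - h.paddy_in_use()
    else:
        capacity = h.unused_regular_fields()
    n = min(intended, max(0, capacity))
    if n < intended:
        state.log_event("plant-shortfall", f"H{h.id} {crop}: {n}/{intended}")
    if n <= 0:
        return None
    day = state.clock.day_index
    pl = Planting(crop=crop, n_fields=n, plant_index=day,
                  harvest_index=day + cp.growth_days, paddy=crop == "rice")
    h.plantings.append(pl)
    if charge:
        state.ledger.post(day, h.account, "crop input",
                          -n * planting_cost_per_field(cp, state.params))
        if not _has_plough_animal(h, state):
            state.ledger.post(day, h.account, "oxen hire",
                              -n * state.params.oxen_hire_cost_per_field)
    return pl


def effective_multiplier(state: VillageState, pl: Planting) -> float:
    """Scenario-adjusted yield multiplier for a planting harvested today."""
    year = max(pl.harvest_index // DAYS_PER_YEAR, 0)
    mult = state.yield_multipliers[(year, pl.crop)]
    eq = state.earthquake_timeline
    if eq is not None:
        is_cash = pl.crop in CASH_CROPS
        if is_cash and pl.harvest_index >= eq.shock_day:
            mult *= eq.cash_crop_yield_factor
        if eq.yield_hit_applies(pl.plant_index, pl.harvest_index):
            mult *= eq.in_window_yield_factor
    return mult


def harvest_planting(h: Household, pl: Planting, state: VillageState) -> float:
    """Sell the whole harvest at the fixed market price; free the fields."""
    cp = crop_table(state.params)[pl.crop]
    mult = effective_multiplier(state, pl)
    income = cp.price * cp.standard_yield * mult * 0.5 * pl.n_fields
    day = state.clock.day_index
    state.ledger.post(day, h.account, "crop sale", income)
    if not _has_plough_animal(h, state):
        state.ledger.post(day, h.account, "oxen hire",
                          -pl.n_fields * state.params.oxen_hire_cost_per_field)
    h.plantings.remove(pl)
    return income


def process_household_crops(h: Household, state: VillageState) -> None:
    """P-step for one household: harvest due plantings, then plant any crop
    whose plantation day is today (strategy re-evaluated first)."""
    day = state.clock.day_index
    for pl in [p for p in h.plantings if p.harvest_index <= day]:
        harvest_planting(h, pl, state)
    doy = state.clock.year_day
    crops = crop_table(state.params)
    due = [name for name, cp in crops.items() if cp.plant_day == doy]
    if due:
        update_crop_strategy(h, state)
        for name in due:
            plant_crop(h, name, state)


def initialize_plantings(state: VillageState) -> None:
    """Crops already in the ground on 1 Jan: wheat, cabbage, cauliflower
    (planted the previous autumn).  Fields are marked used; the planting
    costs predate the simulation."""
    crops = crop_table(state.params)
    for h in state.households.values():
        update_crop_strategy(h, state)
        for name in ("wheat", "cabbage", "cauliflower"):
            cp = crops[name]
            n = min(h.crop_strategy.get(name, 0), h.unused_regular_fields())
            if n <= 0:
                continue
            plant_index = cp.plant_day - 1 - DAYS_PER_YEAR
            h.plantings.append(Planting(
                crop=name, n_fields=n, plant_index=plant_index,
                harvest_index=plant_index + cp.growth_days))


# --------------------------------------------------------------------------
# Polytunnels
# --------------------------------------------------------------------------

POLYTUNNEL_MAINTENANCE_DOY = 46
POLYTUNNEL_PLANTING_DOY = 98
# Fortnightly harvests from day 213 until day 44 of the next year:
# 213 + 14k for k = 0..14 (day 409 wraps to day 44).
POLYTUNNEL_HARVEST_DOYS = frozenset((d - 1) % DAYS_PER_YEAR + 1
                                    for d in range(213, 410, 14))


def step_polytunnel(h: Household, state: VillageState) -> None:
    if h.polytunnels <= 0:
        return
    p = state.params
    doy = state.clock.year_day
    day = state.clock.day_index
    n = h.polytunnels
    if doy == POLYTUNNEL_MAINTENANCE_DOY:
        state.ledger.post(day, h.account, "crop input",
                          -n * p.polytunnel_maintenance_cost)
    if doy == POLYTUNNEL_PLANTING_DOY:
        state.ledger.post(day, h.account, "crop input",
                          -n * (p.polytunnel_seed_cost + p.polytunnel_input_cost))
    if doy in POLYTUNNEL_HARVEST_DOYS:
        state.ledger.post(day, h.account, "tomato",
                          n * p.tomato_income_per_harvest)
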