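import numpy as np
import pytest

from nepalsim.agriculture import (POLYTUNNEL_HARVEST_DOYS,
                                  allocate_cash_crop_fields,
                                  calibrate_yield_distribution,
                                  forecast_yields, harvest_planting,
                                  plant_crop, planting_cost_per_field,
                                  step_polytunnel, update_crop_strategy)
from nepalsim.clock import DAYS_PER_YEAR
from nepalsim.entities import Animal, Planting
from nepalsim.params import crop_table


# -- yield calibration ------------------------------------------------------

@pytest.mark.parametrize("T", [12, 10, 9, 7])
def test_calibrated_half_yield_mass(T):
    d = calibrate_yield_distribution(T)
    assert d.cdf(0.5) == pytest.approx(1.0 / T, abs=1e-4)


def test_calibrated_mode_is_one():
    for T in (12, 7):
        d = calibrate_yield_distribution(T)
        assert d.mode() == pytest.approx(1.0, abs=1e-6)


def test_half_yield_frequency_empirical():
    d = calibrate_yield_distribution(12)
    rng = np.random.default_rng(8)
    n = 100_000
    draws = rng.beta(d.alpha, d.beta, n) * d.support_max
    freq = (draws <= 0.5).mean()
    p = 1 / 12
    assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_infeasible_calibration_raises():
    with pytest.raises(ValueError):
        calibrate_yield_distribution(1.5)  # tail mass above the uniform limit


# -- forecasting ------------------------------------------------------------

def test_smoothing_fixed_point_and_degenerate_alpha():
    assert forecast_yields([0.8] * 10, alpha=0.3) == pytest.approx(0.8)
    assert forecast_yields([1.0, 0.2, 0.9], alpha=1.0) == pytest.approx(0.9)


def test_smoothing_matches_recursion_oracle():
    history = [1.0] * 9 + [0.5]
    alpha = 0.3
    s = history[0]
    for y in history[1:]:
        s = alpha * y + (1 - alpha) * s
    assert forecast_yields(history, alpha) == pytest.approx(s)
    assert s == pytest.approx(0.85)  # only the last year deviates


# -- cash-crop allocation ---------------------------------------------------

def test_standard_ratio_allocation():
    assert allocate_cash_crop_fields(32) == \
        {"potato": 20, "cabbage": 9, "cauliflower": 3}


def test_largest_remainder_with_priority():
    # quotas 5.0 / 2.25 / 0.75: the leftover field goes to the largest
    # remainder (cauliflower)
    assert allocate_cash_crop_fields(8) == \
        {"potato": 5, "cabbage": 2, "cauliflower": 1}


@pytest.mark.parametrize("surplus", range(0, 61))
def test_allocation_preserves_totals(surplus):
    alloc = allocate_cash_crop_fields(surplus)
    assert sum(alloc.values()) == surplus
    assert all(v >= 0 for v in alloc.values())


# -- planting and harvest ---------------------------------------------------

def test_planting_cost_oracles(params):
    crops = crop_table(params)
    # maize: (0.8 kg x 25 + 313) / 2 per half-ropani field
    assert planting_cost_per_field(crops["maize"], params) == pytest.approx(166.5)
    # cabbage: flat 300/ropani seed + 150/ropani fertiliser, halved
    assert planting_cost_per_field(crops["cabbage"], params) == pytest.approx(225.0)


def test_household_with_ox_pays_no_hire(fresh_state):
    state = fresh_state
    h = next(iter(state.households.values()))
    ox = Animal(id=state.new_animal_id(), species="cattle", sex="m",
                age_days=2000, household_id=h.id)
    state.animals[ox.id] = ox
    state.clock.day_index = 56  # maize plantation day (day 57 of the year)
    h.crop_strategy = {"maize": 1}
    h.plantings.clear()
    mark = len(state.ledger.entries)
    plant_crop(h, "maize", state)
    cats = [e.category for e in state.ledger.entries[mark:]]
    assert "oxen hire" not in cats
    assert "crop input" in cats


def test_potato_harvest_income_oracle(fresh_state):
    state = fresh_state
    h = next(iter(state.households.values()))
    for a in list(state.animals.values()):  # ensure an oxen-hire-free check
        if a.household_id == h.id:
            del state.animals[a.id]
    ox = Animal(id=state.new_animal_id(), species="buffalo", sex="m",
                age_days=2000, household_id=h.id)
    state.animals[ox.id] = ox
    pl = Planting(crop="potato", n_fields=1, plant_index=28, harvest_index=169)
    h.plantings.append(pl)
    state.clock.day_index = 169
    state.yield_multipliers[(0, "potato")] = 1.0
    income = harvest_planting(h, pl, state)
    assert income == pytest.approx(22 * 793.1 * 0.5)  # 8,724.1 NPR
    assert pl not in h.plantings


def test_zero_multiplier_harvest_still_incurs_hire(fresh_state):
    state = fresh_state
    h = next(h for h in state.households.values()
             if not any(a.is_bovine and a.sex == "m"
                        for a in state.household_animals(h)))
    pl = Planting(crop="potato", n_fields=2, plant_index=28, harvest_index=169)
    h.plantings.append(pl)
    state.clock.day_index = 169
    state.yield_multipliers[(0, "potato")] = 0.0
    mark = len(state.ledger.entries)
    assert harvest_planting(h, pl, state) == 0.0
    hire = [e for e in state.ledger.entries[mark:] if e.category == "oxen hire"]
    assert len(hire) == 1 and hire[0].amount == -2 * 425


# -- strategy ---------------------------------------------------------------

def test_strategy_pins_paddy_to_rice_and_fills_all_fields(fresh_state):
    state = fresh_state
    h = next(iter(state.households.values()))
    h.paddy_fields = 3
    h.total_fields = max(h.total_fields, 20)
    strategy = update_crop_strategy(h, state)
    assert strategy["rice"] == 3
    cash = strategy["potato"] + strategy["cabbage"] + strategy["cauliflower"]
    grain = strategy["maize"] + strategy["millet"] + strategy["wheat"]
    assert grain + cash == h.regular_fields


def test_grain_self_sufficiency_under_modal_yields(fresh_state):
    # with multiplier 1 forecasts, the planned grain fields cover the need
    state = fresh_state
    h = next(iter(state.households.values()))
    h.total_fields = 60
    for y in range(-10, 1):
        for g in ("maize", "millet", "wheat"):
            state.yield_multipliers[(y, g)] = 1.0
    from nepalsim.agriculture import household_grain_need_kg
    strategy = update_crop_strategy(h, state)
    crops = crop_table(state.params)
    need = household_grain_need_kg(h, state)
    for g in ("maize", "millet", "wheat"):
        assert strategy[g] * crops[g].standard_yield * 0.5 >= need[g]


# -- polytunnels ------------------------------------------------------------

def test_polytunnel_harvest_schedule_enumeration():
    # fortnightly from day 213 to day 44 of the next year (409 = 365 + 44)
    expected = {(d - 1) % DAYS_PER_YEAR + 1 for d in range(213, 410, 14)}
    assert POLYTUNNEL_HARVEST_DOYS == frozenset(expected)
    assert len(POLYTUNNEL_HARVEST_DOYS) == 15
    assert 213 in POLYTUNNEL_HARVEST_DOYS and 44 in POLYTUNNEL_HARVEST_DOYS


def test_polytunnel_cashflows(fresh_state):
    state = fresh_state
    h = next(iter(state.households.values()))
    h.polytunnels = 2
    state.clock.day_index = 212  # day 213 of year one: a harvest day
    mark = len(state.ledger.entries)
    step_polytunnel(h, state)
    tomato = [e for e in state.ledger.entries[mark:] if e.category == "tomato"]
    assert len(tomato) == 1 and tomato[0].amount == 2 * 4140
    h2 = next(hh for hh in state.households.values() if hh.polytunnels == 0)
    mark = len(state.ledger.entries)
    step_polytunnel(h2, state)
    assert len(state.ledger.entries) == mark
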