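"""Household and villager finances.

A villager's money is managed by their *finance controller*: the household
itself for most members, or the villager himself in the case of a
referent's son who has finished his education (he then also manages his
wife's and children's finances).  Controllers receive all income, pay all
expenses, borrow at 20 %/year when they run dry, and once a month make a
conservative twelve-month forecast to decide debt repayments, reconstruction
-loan instalments, and how many weekly meat portions they can afford.

Household fission also lives here: an elder married son claims his land
entitlement E = F/(S+1) and builds his own house once he can afford it, or
emigrates if the entitlement is below six ropani.
"""

from __future__ import annotations

import math

import numpy as np

from .clock import (DAYS_PER_YEAR, day_of_year, is_month_first_day,
                    is_month_last_day, is_sunday)
from .entities import Household, VillageState, Villager
from .ledger import Account
from .params import (ADULT_FEMALE_STAPLE_COST, FOOD_BASKET,
                     consumption_multiplier, crop_table)
from .livestock import (LAYING_ON_DAYS, LAYING_OFF_DAYS, LAYING_START_AGE,
                        daily_feed_cost, rebalance_animals, species_table)
from .agriculture import (forecast_multiplier, planting_cost_per_field,
                          POLYTUNNEL_HARVEST_DOYS, POLYTUNNEL_MAINTENANCE_DOY,
                          POLYTUNNEL_PLANTING_DOY, _has_plough_animal)

SALARY_PARAM_BY_CAREER = {
    "salaried-1": "level1_job_salary",
    "salaried-2": "level2_job_salary",
    "salaried-3": "level3_job_salary",
    "salaried-4": "level4_job_salary",
    "salaried-abroad": "foreign_job_salary",
}

MIN_FISSION_ENTITLEMENT_FIELDS = 12  # six ropani


def daily_interest_rate(annual_rate: float) -> float:
    """Daily compounding rate such that unpaid debt grows by exactly the
    annualised rate over 365 days."""
    return (1.0 + annual_rate) ** (1.0 / DAYS_PER_YEAR) - 1.0


# --------------------------------------------------------------------------
# Controllers and referents
# --------------------------------------------------------------------------

def update_referent(state: VillageState, h: Household) -> None:
    """The referent is the youngest adult male with no siblings in the
    household, else the youngest widowed adult female."""
    members = state.household_members(h)

    def has_sibling_here(v: Villager) -> bool:
        for o in members:
            if o.id == v.id:
                continue
            if (v.mother_id is not None and v.mother_id == o.mother_id) or \
                    (v.father_id is not None and v.father_id == o.father_id):
                return True
        return False

    males = sorted((v for v in members if v.sex == "m" and v.is_adult
                    and not has_sibling_here(v)), key=lambda v: v.age_days)
    if males:
        h.referent_id = males[0].id
        return
    widows = sorted((v for v in members if v.sex == "f" and v.is_adult
                     and v.widowed), key=lambda v: v.age_days)
    if widows:
        h.referent_id = widows[0].id
        return
    adults = sorted((v for v in members if v.is_adult), key=lambda v: v.age_days)
    if adults:
        h.referent_id = adults[0].id
    elif members:
        h.referent_id = max(members, key=lambda v: v.age_days).id


def update_finance_controllers(state: VillageState, h: Household) -> None:
    """E-rule controller assignment: education-complete sons of the referent
    control themselves, their wives, and their children; everyone else is
    managed by the household."""
    referent = state.villagers.get(h.referent_id) if h.referent_id is not None \
        else None
    members = state.household_members(h)
    independent: dict[int, Account] = {}
    if referent is not None:
        for v in members:
            if v.sex == "m" and not v.in_education and \
                    v.father_id == referent.id:
                acc_id = f"V{v.id}"
                if acc_id not in state.accounts:
                    state.accounts[acc_id] = Account(id=acc_id)
                independent[v.id] = state.accounts[acc_id]
    for v in members:
        if v.id in independent:
            v.controller_id = independent[v.id].id
        elif v.partner_id in independent:
            v.controller_id = independent[v.partner_id].id
        elif v.father_id in independent and not v.is_adult:
            v.controller_id = independent[v.father_id].id
        else:
            v.controller_id = h.account.id


def controlled_villagers(state: VillageState, acc_id: str) -> list[Villager]:
    return [v for v in state.villagers.values() if v.controller_id == acc_id]


# --------------------------------------------------------------------------
# Daily income and expenses
# --------------------------------------------------------------------------

def labour_availability(state: VillageState) -> float:
    """Today's probability that a short-term labourer finds work."""
    p = state.params.labouring_probability
    eq = state.earthquake_timeline
    if eq is not None:
        p *= eq.labour_factor(state.clock.day_index)
    return min(1.0, p)


def daily_income(v: Villager, state: VillageState) -> None:
    day = state.clock.day_index
    acc = state.account_of(v)
    p = state.params
    v.worked_today = False
    if v.career in SALARY_PARAM_BY_CAREER:
        if is_month_last_day(day):
            state.ledger.post(day, acc, "salary", p[SALARY_PARAM_BY_CAREER[v.career]])
    elif v.career == "labourer":
        if not state.clock.is_festival() and \
                state.rng.labour.uniform() < labour_availability(state):
            v.worked_today = True
            state.ledger.post(day, acc, "wage", p.labouring_wage)
    elif v.career == "pensioner":
        if is_month_first_day(day):
            state.ledger.post(day, acc, "pension", p.pension_income)


def food_cost(v: Villager, state: VillageState) -> float:
    """Today's food bill for one villager (staple basket plus other food,
    scaled by the age-sex consumption multiplier).  Halved when the main
    meal is eaten away from the village; zero while abroad."""
    if v.abroad:
        return 0.0
    p = state.params
    base = (ADULT_FEMALE_STAPLE_COST + p.other_food_expenses) * \
        consumption_multiplier(v.sex, v.age_years)
    if v.career == "labourer":
        if v.worked_today:
            base *= 0.5
    elif (v.career.startswith("salaried-") and v.career != "salaried-abroad") or \
            v.education in ("school", "plus2"):
        if not state.clock.is_festival():
            base *= 0.5
    return base


def daily_expenses(v: Villager, state: VillageState) -> None:
    day = state.clock.day_index
    acc = state.account_of(v)
    p = state.params
    if not v.abroad:
        state.ledger.post(day, acc, "food", -food_cost(v, state))
        state.ledger.post(day, acc, "other living", -p.other_living_expenses)
        if state.clock.is_festival():
            state.ledger.post(day, acc, "festival", -p.festival_expenses)
        if is_sunday(day) and acc.meat_portions > 0:
            cost = acc.meat_portions * p.meat_portion_cost * \
                consumption_multiplier(v.sex, v.age_years)
            state.ledger.post(day, acc, "meat", -cost)
    if is_month_first_day(day):
        if v.education == "school":
            state.ledger.post(day, acc, "education", -p.monthly_school_expenses)
        elif v.education == "plus2":
            state.ledger.post(day, acc, "education", -p.monthly_college_expenses)


# --------------------------------------------------------------------------
# Twelve-month conservative forecast
# --------------------------------------------------------------------------

def _calendar_flags(state: VillageState, upto: int):
    """Cached boolean calendars (month-first, month-last, festival, Sunday)
    indexed by absolute day index."""
    flags = getattr(state, "_calendar_flags", None)
    if flags is None or len(flags[0]) < upto:
        n = max(upto, state.clock.day_index + 2 * DAYS_PER_YEAR)
        idx = np.arange(n)
        doy = idx % DAYS_PER_YEAR + 1
        month_first = np.array([is_month_first_day(i) for i in range(n)])
        month_last = np.array([is_month_last_day(i) for i in range(n)])
        festival = np.isin(doy, list(state.clock.festival_days))
        sunday = np.array([is_sunday(i) for i in range(n)])
        flags = (month_first, month_last, festival, sunday)
        state._calendar_flags = flags
    return flags


def _next_doy_offset(today: int, doy: int) -> int:
    """Days from `today` to the next strict-future occurrence of a day of
    year, in 1..365."""
    return (doy - day_of_year(today)) % DAYS_PER_YEAR or DAYS_PER_YEAR


def forecast_cashflow(acc: Account, state: VillageState,
                      meat_portions: int | None = None,
                      include_recon: bool = False,
                      household: Household | None = None) -> np.ndarray:
    """Deterministic daily balance path over the coming 365 days.

    Conservative in the model's sense: all scheduled outgoings are included
    (food at the full, unhalved rate), crop income enters at the smoothed
    forecast multiplier, labouring at its expected daily rate, and windfalls
    (animal sales, wedding gifts) are excluded.
    """
    p = state.params
    d0 = state.clock.day_index
    horizon = DAYS_PER_YEAR
    month_first, month_last, festival, sunday = _calendar_flags(state, d0 + horizon + 2)
    sl = slice(d0 + 1, d0 + 1 + horizon)
    deltas = np.zeros(horizon)

    deps = controlled_villagers(state, acc.id)
    meat = acc.meat_portions if meat_portions is None else meat_portions
    daily_out = 0.0
    daily_in = 0.0
    mfirst = 0.0
    mlast = 0.0
    festival_out = 0.0
    meat_weekly = 0.0
    for v in deps:
        mult = consumption_multiplier(v.sex, v.age_years)
        if not v.abroad:
            daily_out += (ADULT_FEMALE_STAPLE_COST + p.other_food_expenses) * mult \
                + p.other_living_expenses
            festival_out += p.festival_expenses
            meat_weekly += meat * p.meat_portion_cost * mult
        if v.career in SALARY_PARAM_BY_CAREER:
            mlast += p[SALARY_PARAM_BY_CAREER[v.career]]
        elif v.career == "labourer":
            daily_in += labour_availability(state) * p.labouring_wage
        elif v.career == "pensioner":
            mfirst += p.pension_income
        if v.education == "school":
            mfirst -= p.monthly_school_expenses
        elif v.education == "plus2":
            mfirst -= p.monthly_college_expenses

    if household is not None:
        if household.remittance:
            mfirst += p.remittance_income
        table = species_table(p)
        hh_size = len(household.member_ids)
        for a in state.household_animals(household):
            daily_out += daily_feed_cost(table[a.species], p)
            if a.species == "chicken" and a.sex == "f" and \
                    a.age_days >= LAYING_START_AGE:
                daily_in += p.egg_sale_price * LAYING_ON_DAYS / \
                    (LAYING_ON_DAYS + LAYING_OFF_DAYS)
            elif a.sex == "f" and hh_size in (1, 2):
                if a.species == "cattle":
                    rate = p.cow_milk_income_size1 if hh_size == 1 \
                        else p.cow_milk_income_size2
                    daily_in += rate * 10 / 12
                elif a.species == "buffalo":
                    rate = p.buffalo_milk_income_size1 if hh_size == 1 \
                        else p.buffalo_milk_income_size2
                    daily_in += rate * 10 / 12
        crops = crop_table(p)
        plough = _has_plough_animal(household, state)
        for pl in household.plantings:
            off = pl.harvest_index - d0
            if 1 <= off <= horizon:
                cp = crops[pl.crop]
                fm = forecast_multiplier(state, pl.crop)
                deltas[off - 1] += cp.price * cp.standard_yield * fm * 0.5 * pl.n_fields
                if not plough:
                    deltas[off - 1] -= pl.n_fields * p.oxen_hire_cost_per_field
        for name, cp in crops.items():
            n = household.crop_strategy.get(name, 0)
            if n <= 0:
                continue
            plant_off = _next_doy_offset(d0, cp.plant_day)
            if plant_off <= horizon:
                cost = n * planting_cost_per_field(cp, p)
                if not plough:
                    cost += n * p.oxen_hire_cost_per_field
                deltas[plant_off - 1] -= cost
                harv_off = plant_off + cp.growth_days
                if harv_off <= horizon:
                    fm = forecast_multiplier(state, name)
                    deltas[harv_off - 1] += \
                        cp.price * cp.standard_yield * fm * 0.5 * n
                    if not plough:
                        deltas[harv_off - 1] -= n * p.oxen_hire_cost_per_field
        if household.polytunnels > 0:
            nt = household.polytunnels
            off = _next_doy_offset(d0, POLYTUNNEL_MAINTENANCE_DOY)
            deltas[off - 1] -= nt * p.polytunnel_maintenance_cost
            off = _next_doy_offset(d0, POLYTUNNEL_PLANTING_DOY)
            deltas[off - 1] -= nt * (p.polytunnel_seed_cost + p.polytunnel_input_cost)
            for doy in POLYTUNNEL_HARVEST_DOYS:
                off = _next_doy_offset(d0, doy)
                deltas[off - 1] += nt * p.tomato_income_per_harvest

    deltas += daily_in - daily_out
    deltas[festival[sl]] -= festival_out
    deltas[sunday[sl]] -= meat_weekly
    deltas[month_first[sl]] += mfirst
    deltas[month_last[sl]] += mlast
    if include_recon and acc.reconstruction_loan > 0:
        deltas[month_first[sl]] -= min(acc.recon_instalment,
                                       acc.reconstruction_loan)
    return acc.cash + np.cumsum(deltas)


# --------------------------------------------------------------------------
# Daily and monthly finance assessment
# --------------------------------------------------------------------------

def assess_finances(acc: Account, state: VillageState,
                    household: Household | None = None) -> None:
    """End-of-day stock-take for one finance controller.

    Daily: cover any overdraft (a household first asks its richest
    independent member, then borrows) and accrue interest.  On the first of
    the month: forecast the year ahead, repay ordinary debt down to the
    forecast minimum balance, pay a reconstruction instalment when debt-free
    and affordable, then set the weekly meat portions."""
    day = state.clock.day_index
    ledger = state.ledger
    p = state.params

    if acc.cash < 0:
        shortfall = -acc.cash
        covered = False
        if household is not None:
            member_accs = sorted(
                (state.accounts[f"V{v.id}"] for v in
                 state.household_members(household)
                 if f"V{v.id}" in state.accounts
                 and state.accounts[f"V{v.id}"] is not acc),
                key=lambda a: -a.cash)
            if member_accs and member_accs[0].cash >= shortfall:
                ledger.transfer(day, member_accs[0], acc, "bailout", shortfall)
                covered = True
        if not covered:
            acc.debt += shortfall
            ledger.post(day, acc, "loan principal", shortfall)

    if acc.debt > 0:
        acc.debt *= 1.0 + daily_interest_rate(p.annual_interest_rate)

    if not is_month_first_day(day):
        return

    path = forecast_cashflow(acc, state, meat_portions=0, household=household)
    min_balance = float(path.min())
    if acc.debt > 0 and min_balance > 0:
        repay = min(acc.debt, min_balance)
        ledger.post(day, acc, "repayment", -repay)
        acc.debt -= repay
        if acc.debt < 1e-9:
            acc.debt = 0.0
        min_balance -= repay
    recon_annual = 0.0
    if acc.reconstruction_loan > 0 and acc.debt == 0:
        inst = min(acc.recon_instalment, acc.reconstruction_loan)
        recon_annual = 12 * inst
        if min_balance - recon_annual >= 0 and acc.cash >= inst:
            ledger.post(day, acc, "repayment", -inst)
            acc.reconstruction_loan -= inst
            min_balance -= inst

    weekly_per_portion = sum(
        p.meat_portion_cost * consumption_multiplier(v.sex, v.age_years)
        for v in controlled_villagers(state, acc.id) if not v.abroad)
    portions = 0
    for k in (3, 2, 1):
        if min_balance - recon_annual - 52 * k * weekly_per_portion >= 0:
            portions = k
            break
    acc.meat_portions = portions


# --------------------------------------------------------------------------
# Household fission
# --------------------------------------------------------------------------

def _round_to_field(x: float) -> int:
    return int(math.floor(x + 0.5))


def fission_entitlement_fields(total_fields: int, sons_in_household: int) -> int:
    """E = F/(S+1), rounded to the nearest field (half ropani)."""
    return _round_to_field(total_fields / (sons_in_household + 1))


def household_fission_check(h: Household, state: VillageState) -> None:
    """Elder married sons split off (or emigrate) when their turn comes."""
    referent = state.villagers.get(h.referent_id) if h.referent_id is not None \
        else None
    if referent is None:
        return
    sons = [state.villagers[c] for c in referent.children_ids
            if c in state.villagers and state.villagers[c].sex == "m"
            and state.villagers[c].household_id == h.id]
    if len(sons) < 2:
        return  # a lone son inherits; no fission
    youngest_id = min(sons, key=lambda s: s.age_days).id
    p = state.params
    for son in sons:
        if son.id == youngest_id or not son.married or son.in_education \
                or son.abroad:
            continue
        wife = state.villagers.get(son.partner_id)
        if wife is None or wife.household_id != h.id:
            continue
        entitlement = fission_entitlement_fields(h.total_fields, len(sons))
        if entitlement < MIN_FISSION_ENTITLEMENT_FIELDS:
            leavers = [son.id, wife.id] + [c for c in son.children_ids
                                           if c in state.villagers]
            acc = state.accounts.get(f"V{son.id}")
            if acc is not None and acc.cash != 0.0:
                state.ledger.post(state.clock.day_index, acc, "other", -acc.cash)
            state.log_event("fission-emigration", f"villager {son.id} household H{h.id}")
            from .demography import depart_household_members
            depart_household_members(state, leavers)
            return
        acc = state.accounts.get(f"V{son.id}")
        if acc is None or acc.cash < p.house_construction_cost + p.fission_cash_buffer:
            continue
        _execute_fission(state, h, son, wife, acc, entitlement)
        return


def _execute_fission(state: VillageState, parent: Household, son: Villager,
                     wife: Villager, acc: Account, entitlement: int) -> None:
    day = state.clock.day_index
    p = state.params
    state.ledger.post(day, acc, "house construction", -p.house_construction_cost)
    new_id = state.new_household_id()
    new_acc_id = f"H{new_id}"
    new_acc = Account(id=new_acc_id)
    state.accounts[new_acc_id] = new_acc
    new_h = Household(id=new_id, archetype="fissioned", account=new_acc)
    state.households[new_id] = new_h
    movers = [son, wife] + [state.villagers[c] for c in son.children_ids
                            if c in state.villagers]
    for v in movers:
        if v.id in parent.member_ids:
            parent.member_ids.remove(v.id)
        new_h.member_ids.append(v.id)
        v.household_id = new_id
    new_h.referent_id = son.id
    # the couple's remaining cash becomes the new household's stock
    state.ledger.transfer(day, acc, new_acc, "other", acc.cash)
    new_acc.debt, acc.debt = acc.debt, 0.0
    # claim unused regular fields now; the rest arrives as harvests free them
    take = min(entitlement, parent.unused_regular_fields())
    parent.total_fields -= take
    new_h.total_fields += take
    if entitlement > take:
        parent.pending_field_claims[new_id] = entitlement - take
    update_finance_controllers(state, parent)
    update_finance_controllers(state, new_h)
    rebalance_animals(new_h, state)
    state.log_event("fission", f"villager {son.id} founds H{new_id} "
                               f"({entitlement} fields)")


def settle_field_claims(h: Household, state: VillageState) -> None:
    """Transfer freed (non-paddy) fields towards outstanding fission
    entitlements."""
    if not h.pending_field_claims:
        return
    for new_id in list(h.pending_field_claims):
        if new_id not in state.households:
            del h.pending_field_claims[new_id]
            continue
        owed = h.pending_field_claims[new_id]
        take = min(owed, h.unused_regular_fields())
        if take <= 0:
            continue
        h.total_fields -= take
        state.households[new_id].total_fields += take
        if owed - take > 0:
            h.pending_field_claims[new_id] = owed - take
        else:
            del h.pending_field_claims[new_id]


# --------------------------------------------------------------------------
# Financial initialisation
# --------------------------------------------------------------------------

def _career_annual_income(v: Villager, state: VillageState) -> float:
    p = state.params
    if v.career in SALARY_PARAM_BY_CAREER:
        return 12 * p[SALARY_PARAM_BY_CAREER[v.career]]
    if v.career == "labourer":
        return p.labouring_probability * p.labouring_wage * \
            (DAYS_PER_YEAR - len(state.clock.festival_days))
    if v.career == "pensioner":
        return 12 * p.pension_income
    return 0.0


def _personal_annual_expenses(v: Villager, state: VillageState) -> float:
    if v.abroad:
        return 0.0
    p = state.params
    mult = consumption_multiplier(v.sex, v.age_years)
    return ((ADULT_FEMALE_STAPLE_COST + p.other_food_expenses) * mult
            + p.other_living_expenses) * DAYS_PER_YEAR \
        + len(state.clock.festival_days) * p.festival_expenses


def initialize_finances(state: VillageState,
                        net_finance_samples: list[float]) -> None:
    """Starting cash via the two-step rule: each controller holds exactly
    what the year ahead requires (at two meat portions a week and expected
    yields), households add a sampled-without-replacement historical net
    position, two households draw a remittance, and independent sons hold
    their estimated savings since leaving education."""
    rng = state.rng.finance
    households = sorted(state.households.values(), key=lambda h: h.id)
    for h in households:
        update_referent(state, h)
        update_finance_controllers(state, h)
    # two remittance households (assigned before cash needs are computed)
    idx = rng.choice(len(households), size=min(2, len(households)), replace=False)
    for i in np.atleast_1d(idx):
        households[int(i)].remittance = True
    if len(net_finance_samples) < len(households):
        raise ValueError("reference net-finance set smaller than household count")
    sampled = rng.choice(len(net_finance_samples), size=len(households),
                         replace=False)

    for h, si in zip(households, sampled):
        acc = h.account
        acc.meat_portions = 2
        path = forecast_cashflow(acc, state, meat_portions=2, household=h)
        required = max(0.0, -float(path.min() - acc.cash))
        acc.cash = required
        net = float(net_finance_samples[int(si)])
        if net >= 0:
            acc.cash += net
        else:
            acc.debt += -net

    for h in households:
        for v in state.household_members(h):
            acc = state.accounts.get(f"V{v.id}")
            if acc is None or v.controller_id != acc.id:
                continue
            acc.meat_portions = 2
            path = forecast_cashflow(acc, state, meat_portions=2)
            acc.cash = max(0.0, -float(path.min() - acc.cash))
            end_age = PLUS2_END_DAYS if v.attainment == "plus2" else SCHOOL_END_DAYS
            years_since = max(0.0, (v.age_days - end_age) / DAYS_PER_YEAR)
            surplus = max(0.0, _career_annual_income(v, state)
                          - _personal_annual_expenses(v, state))
            acc.cash += years_since * surplus


# education-span constants mirrored from the demography thresholds
SCHOOL_END_DAYS = 5740
PLUS2_END_DAYS = 6570
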