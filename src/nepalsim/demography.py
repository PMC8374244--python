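"""Life-course processes: education and career, death, marriage, and birth.

Education change points fire on day 100 of the year (the approximate start
of the school calendar); all other career change points fire on birthdays.
Deaths and marriages are pre-scheduled ages drawn from the mortality and
marriage-age distributions; births are scheduled from the first-birth-delay
and birth-interval distributions as a woman progresses towards her desired
number of children.  When a death and a marriage would fall on the same
day, the death wins, so nobody acts after dying.
"""

from __future__ import annotations

import numpy as np

from .clock import DAYS_PER_YEAR
from .distributions import draw_desired_children
from .entities import VillageState, Villager
from .ledger import Account
from .synthesis import SynthesisReferenceData, _draw, _nearest_key

SCHOOL_START_AGE_DAYS = 2090
SCHOOL_END_AGE_DAYS = 5740
PLUS2_END_AGE_DAYS = 6570
SCHOOL_YEAR_START_DOY = 100

# Parity cutoffs (years): a childless woman married longer than the first is
# assumed to desire no children; a woman whose last birth is older than the
# second is assumed to desire no more.
CHILDLESS_MARRIAGE_CUTOFF_YEARS = 9.78
LAST_BIRTH_CUTOFF_YEARS = 9.86

PREGNANCY_DAYS = 270  # nine months


# --------------------------------------------------------------------------
# Careers
# --------------------------------------------------------------------------

def _post_education_career(v: Villager, state: VillageState,
                           rng: np.random.Generator) -> None:
    """Assign a career on leaving education.  Only the salaried-entry
    probability is empirically anchored; the abroad/labourer split is a
    configurable default."""
    p = state.params
    if v.attainment == "plus2" and rng.uniform() < p.prob_salaried_after_plus2:
        v.career = "salaried-1"
        return
    if v.sex == "m":
        if rng.uniform() < p.prob_abroad_after_education:
            v.career = "salaried-abroad"
            v.abroad = True
            return
        if rng.uniform() < p.prob_labourer_after_education:
            v.career = "labourer"
            return
    v.career = "farm"


def _promotion_prob(state: VillageState, level: int) -> float:
    p = state.params
    return {1: p.prob_advance_level2, 2: p.prob_advance_level3,
            3: p.prob_advance_level4}.get(level, 0.0)


def update_career(v: Villager, state: VillageState) -> None:
    """Education junctures on day 100 of the year; other change points on
    birthdays."""
    rng = state.rng.demography
    p = state.params
    if state.clock.year_day == SCHOOL_YEAR_START_DOY:
        if v.education == "pre-school" and v.age_days >= SCHOOL_START_AGE_DAYS:
            v.education = "school"
            v.career = "student"
        elif v.education == "school" and v.age_days >= SCHOOL_END_AGE_DAYS:
            if rng.uniform() < p.prob_plus2_post_school:
                v.education = "plus2"
                v.attainment = "SLC"
                v.career = "student"
            else:
                v.education = "left"
                if rng.uniform() < p.prob_slc_on_leaving_school:
                    v.attainment = "SLC"
                _post_education_career(v, state, rng)
        elif v.education == "plus2" and v.age_days >= PLUS2_END_AGE_DAYS:
            v.education = "left"
            v.attainment = "plus2"
            _post_education_career(v, state, rng)
    if v.age_days % DAYS_PER_YEAR == 0:
        age_years = v.age_days // DAYS_PER_YEAR
        if v.career.startswith("salaried-") and v.career != "salaried-abroad":
            level = int(v.career[-1])
            if age_years in [int(a) for a in p.salaried_promotion_ages] and level < 4:
                if rng.uniform() < _promotion_prob(state, level):
                    v.career = f"salaried-{level + 1}"
            if age_years >= p.retirement_age:
                v.career = "pensioner"
        elif v.career == "salaried-abroad" and age_years >= p.abroad_return_age:
            v.career = "farm"
            v.abroad = False


# --------------------------------------------------------------------------
# Removal helpers
# --------------------------------------------------------------------------

def _unlink(state: VillageState, v: Villager) -> None:
    """Drop all references to a villager so nothing dangles."""
    if v.partner_id is not None and v.partner_id in state.villagers:
        state.villagers[v.partner_id].partner_id = None
    for pid in (v.mother_id, v.father_id):
        if pid is not None and pid in state.villagers:
            kids = state.villagers[pid].children_ids
            if v.id in kids:
                kids.remove(v.id)
    for cid in v.children_ids:
        if cid in state.villagers:
            child = state.villagers[cid]
            if child.mother_id == v.id:
                child.mother_id = None
            if child.father_id == v.id:
                child.father_id = None


def remove_villager(state: VillageState, v: Villager, *, death: bool) -> None:
    h = state.households.get(v.household_id)
    if h is not None and v.id in h.member_ids:
        h.member_ids.remove(v.id)
    _unlink(state, v)
    v.alive = False
    del state.villagers[v.id]
    if death:
        state.deaths += 1
    else:
        state.departures += 1


def remove_household(state: VillageState, hid: int) -> None:
    """House, fields, and animals cease to exist; the account is closed at
    zero (any residual cash leaves the model and is posted as such)."""
    h = state.households.pop(hid, None)
    if h is None:
        return
    for a in [a for a in state.animals.values() if a.household_id == hid]:
        del state.animals[a.id]
    acc = h.account
    if acc.cash != 0.0:
        state.ledger.post(state.clock.day_index, acc, "other", -acc.cash)
    acc.debt = 0.0
    acc.reconstruction_loan = 0.0
    state.log_event("household-removed", f"H{hid}")


def depart_household_members(state: VillageState, vids: list[int]) -> None:
    for vid in list(vids):
        if vid in state.villagers:
            remove_villager(state, state.villagers[vid], death=False)


# --------------------------------------------------------------------------
# Death
# --------------------------------------------------------------------------

def process_death(v: Villager, state: VillageState) -> None:
    day = state.clock.day_index
    h = state.households.get(v.household_id)
    partner = state.villagers.get(v.partner_id) if v.partner_id is not None else None

    if partner is not None:
        partner.widowed = True
        if partner.next_birth_day is not None and \
                partner.next_birth_day > day + PREGNANCY_DAYS:
            partner.next_birth_day = None

    own_account = state.accounts.get(f"V{v.id}")
    wife_and_children_leave = False
    if own_account is not None and v.controller_id == own_account.id:
        # a self-controlling man's wife inherits and moves to her own
        # village with the children; the balance leaves the model
        if partner is not None and v.sex == "m":
            wife_and_children_leave = True
            if own_account.cash != 0.0:
                state.ledger.post(day, own_account, "inheritance", -own_account.cash)
            own_account.debt = 0.0
        elif h is not None:
            state.ledger.transfer(day, own_account, h.account, "inheritance",
                                  own_account.cash)
            h.account.debt += own_account.debt
            own_account.debt = 0.0

    if h is not None:
        state.ledger.post(day, h.account, "funeral", -state.params.funeral_cost)

    state.log_event("death", f"villager {v.id}")
    minor_children = [state.villagers[c] for c in v.children_ids
                      if c in state.villagers and not state.villagers[c].is_adult]
    # paternal grandparents must be located before kinship links are severed
    if v.sex == "m":
        paternal_grandparent_ids = [pid for pid in (v.mother_id, v.father_id)
                                    if pid is not None]
    else:
        father_of_children = state.villagers.get(v.partner_id) \
            if v.partner_id is not None else None
        paternal_grandparent_ids = [] if father_of_children is None else \
            [pid for pid in (father_of_children.mother_id,
                             father_of_children.father_id) if pid is not None]
    remove_villager(state, v, death=True)

    if wife_and_children_leave and partner is not None:
        leavers = [partner.id] + [c for c in partner.children_ids
                                  if c in state.villagers]
        depart_household_members(state, leavers)

    # orphans: both parents gone -> paternal grandparents in the village
    # adopt, otherwise the children leave for their maternal grandparents
    for child in minor_children:
        if child.id not in state.villagers:
            continue
        mother_alive = child.mother_id in state.villagers
        father_alive = child.father_id in state.villagers
        if mother_alive or father_alive:
            continue
        grandparent = next((state.villagers[g] for g in paternal_grandparent_ids
                            if g in state.villagers), None)
        if grandparent is not None:
            old_h = state.households.get(child.household_id)
            if old_h is not None and child.id in old_h.member_ids:
                old_h.member_ids.remove(child.id)
            new_h = state.households[grandparent.household_id]
            new_h.member_ids.append(child.id)
            child.household_id = new_h.id
            state.log_event("adoption", f"villager {child.id} -> H{new_h.id}")
        else:
            remove_villager(state, child, death=False)

    if h is not None and not h.member_ids:
        remove_household(state, h.id)


# --------------------------------------------------------------------------
# Marriage
# --------------------------------------------------------------------------

def _dowry_payer(state: VillageState, v: Villager) -> Account | None:
    for pid in (v.father_id, v.mother_id):
        if pid is not None and pid in state.villagers:
            return state.accounts[state.villagers[pid].controller_id]
    return None


def initialize_attainment_for_age(v: Villager, state: VillageState,
                                  rng: np.random.Generator) -> None:
    """Educational state by age at initialisation."""
    age = v.age_days
    if age < SCHOOL_START_AGE_DAYS:
        v.education, v.career = "pre-school", "child"
    elif age < SCHOOL_END_AGE_DAYS:
        v.education, v.career = "school", "student"
    elif age < PLUS2_END_AGE_DAYS:
        if rng.uniform() < 0.5:
            v.education, v.attainment, v.career = "plus2", "SLC", "student"
        else:
            v.education = "left"
            v.attainment = "SLC" if rng.uniform() < \
                state.params.prob_slc_on_leaving_school else "none"
    elif v.age_years < 28:
        v.education = "left"
        u = rng.uniform()
        v.attainment = "plus2" if u < 0.25 else ("SLC" if u < 0.5 else "none")
    elif v.age_years < 45:
        v.education = "left"
        v.attainment = "SLC" if rng.uniform() < 0.25 else "none"
    else:
        v.education, v.attainment = "left", "none"


def initialize_career_for_age(v: Villager, state: VillageState,
                              rng: np.random.Generator) -> None:
    """Career pathway at initialisation, via the same branch probabilities
    as the running model, with promotions replayed for ages already passed."""
    if v.in_education:
        return
    p = state.params
    _post_education_career(v, state, rng)
    if v.career.startswith("salaried-") and v.career != "salaried-abroad":
        for promo_age in sorted(p.salaried_promotion_ages):
            if v.age_years >= promo_age:
                level = int(v.career[-1])
                if level < 4 and rng.uniform() < _promotion_prob(state, level):
                    v.career = f"salaried-{level + 1}"
        if v.age_years >= p.retirement_age:
            v.career = "pensioner"
    elif v.career == "salaried-abroad" and v.age_years >= p.abroad_return_age:
        v.career = "farm"
        v.abroad = False


def create_wife(state: VillageState, husband: Villager,
                ref: SynthesisReferenceData) -> Villager:
    """A bride joining the village: aged by the spouse-gap method, with
    schedules drawn the same way as at initialisation."""
    rng = state.rng.demography
    dists = state.distributions
    husband_age_years = husband.age_years
    viable = [g for g in ref.spouse_age_gaps if husband_age_years - g >= 18.0]
    gap = (_draw(rng, viable) + rng.uniform(-0.5, 0.5)) if viable else \
        husband_age_years - 18.0
    age_years = max(18.0, husband_age_years - gap)
    wife = Villager(id=state.new_villager_id(), sex="f",
                    age_days=int(round(age_years * DAYS_PER_YEAR)),
                    household_id=husband.household_id)
    initialize_attainment_for_age(wife, state, rng)
    initialize_career_for_age(wife, state, rng)
    wife.death_age_days = dists.draw_death_age_days("f", rng,
                                                    min_years=wife.age_years)
    wife.married = True
    wife.marriage_age_days = wife.age_days
    wife.marriage_day = state.clock.day_index
    wife.desired_children = draw_desired_children(
        state.scenario.fertility_rate, rng)
    if wife.desired_children > 0:
        wife.next_birth_day = state.clock.day_index + \
            dists.draw_first_birth_delay_days(rng)
    state.villagers[wife.id] = wife
    state.arrivals += 1
    return wife


def process_marriage(v: Villager, state: VillageState,
                     ref: SynthesisReferenceData) -> None:
    day = state.clock.day_index
    params = state.params
    if v.sex == "f":
        # brides leave the village; their parents fund the dowry
        payer = _dowry_payer(state, v)
        if payer is not None:
            state.ledger.post(day, payer, "dowry", -params.dowry_cost)
        state.log_event("marriage-out", f"villager {v.id}")
        remove_villager(state, v, death=False)
        return

    wife = create_wife(state, v, ref)
    h = state.households[v.household_id]
    h.member_ids.append(wife.id)
    v.partner_id, wife.partner_id = wife.id, v.id
    v.married = True
    v.marriage_day = day
    from .finance import update_finance_controllers  # local: avoid cycle
    update_finance_controllers(state, h)
    couple = state.accounts[v.controller_id]
    # the bride's parents live outside the model: their gift is an inflow
    state.ledger.post(day, couple, "wedding", params.wedding_gift)
    groom_parent = _dowry_payer(state, v)
    if groom_parent is not None and groom_parent.id != couple.id:
        state.ledger.transfer(day, groom_parent, couple, "wedding",
                              params.wedding_gift)
    state.log_event("marriage", f"villager {v.id} weds {wife.id}")


# --------------------------------------------------------------------------
# Birth
# --------------------------------------------------------------------------

def process_birth(mother: Villager, state: VillageState) -> None:
    rng = state.rng.demography
    dists = state.distributions
    day = state.clock.day_index
    sex = "m" if rng.uniform() < 0.5 else "f"
    baby = Villager(id=state.new_villager_id(), sex=sex, age_days=0,
                    household_id=mother.household_id,
                    mother_id=mother.id, father_id=mother.partner_id,
                    controller_id=mother.controller_id)
    baby.marriage_age_days = dists.draw_marriage_age_days(sex, rng)
    baby.death_age_days = dists.draw_death_age_days(sex, rng)
    state.villagers[baby.id] = baby
    h = state.households[mother.household_id]
    h.member_ids.append(baby.id)
    mother.children_ids.append(baby.id)
    father = state.villagers.get(mother.partner_id) \
        if mother.partner_id is not None else None
    if father is not None:
        father.children_ids.append(baby.id)
    mother.last_birth_day = day
    state.births += 1
    state.log_event("birth", f"villager {baby.id}")
    n_children = len(mother.children_ids)
    if mother.desired_children is not None and n_children < mother.desired_children:
        mother.next_birth_day = day + dists.draw_birth_interval_days(rng)
    else:
        mother.next_birth_day = None


# --------------------------------------------------------------------------
# Villager schedule initialisation
# --------------------------------------------------------------------------

def initialize_villager_schedules(state: VillageState,
                                  ref: SynthesisReferenceData) -> None:
    """Education, career, marriage age, death age, and fertility for every
    synthesised villager.  Married men's marriage dates are aligned to their
    wives' afterwards, so the couple shares one wedding date."""
    rng = state.rng.demography
    dists = state.distributions
    for v in list(state.villagers.values()):
        initialize_attainment_for_age(v, state, rng)
        initialize_career_for_age(v, state, rng)
        v.death_age_days = dists.draw_death_age_days(v.sex, rng,
                                                     min_years=v.age_years)

    for v in list(state.villagers.values()):
        if v.married and v.sex == "f":
            eldest_age_years = max(
                (state.villagers[c].age_years for c in v.children_ids
                 if c in state.villagers), default=None)
            hi = v.age_years if eldest_age_years is None \
                else v.age_years - eldest_age_years
            v.marriage_age_days = dists.draw_marriage_age_days(
                "f", rng, max_years=hi)
            v.marriage_day = -(v.age_days - v.marriage_age_days)
        elif not v.married:
            if dists.marriage[v.sex].cdf(v.age_years) > 0.999:
                v.marriage_age_days = None  # will not marry
            else:
                v.marriage_age_days = dists.draw_marriage_age_days(
                    v.sex, rng, min_years=v.age_years)

    # husbands share the wife's wedding date
    for v in state.villagers.values():
        if v.married and v.sex == "m" and v.partner_id in state.villagers:
            wife = state.villagers[v.partner_id]
            if wife.marriage_day is not None:
                v.marriage_day = wife.marriage_day
                v.marriage_age_days = v.age_days + wife.marriage_day

    for v in list(state.villagers.values()):
        if not (v.married and v.sex == "f"):
            continue
        if v.age_years >= 50:
            v.desired_children = None
            v.next_birth_day = None
            continue
        n_children = len(v.children_ids)
        years_married = -(v.marriage_day or 0) / DAYS_PER_YEAR
        years_since_birth = (-(v.last_birth_day) / DAYS_PER_YEAR
                             if v.last_birth_day is not None else None)
        if n_children == 0 and years_married > CHILDLESS_MARRIAGE_CUTOFF_YEARS:
            v.desired_children = 0
        elif years_since_birth is not None and \
                years_since_birth > LAST_BIRTH_CUTOFF_YEARS:
            v.desired_children = n_children
        else:
            v.desired_children = draw_desired_children(
                state.scenario.fertility_rate, rng, floor=n_children)
        if v.desired_children > n_children:
            if n_children == 0:
                elapsed = years_married
                delay = dists.draw_first_birth_delay_days(rng, min_years=elapsed)
                v.next_birth_day = (v.marriage_day or 0) + delay
            else:
                elapsed = years_since_birth or 0.0
                interval = dists.draw_birth_interval_days(rng, min_years=elapsed)
                v.next_birth_day = (v.last_birth_day or 0) + interval
            if v.next_birth_day is not None and v.next_birth_day < 1:
                v.next_birth_day = 1  # overdue draws resolve on day 1
        else:
            v.next_birth_day = None
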