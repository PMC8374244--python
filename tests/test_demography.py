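import numpy as np
import pytest
from scipy import stats

from nepalsim.clock import DAYS_PER_YEAR, SimulationClock
from nepalsim.demography import (SCHOOL_END_AGE_DAYS, PLUS2_END_AGE_DAYS,
                                 initialize_attainment_for_age, process_birth,
                                 process_death, process_marriage,
                                 update_career)
from nepalsim.distributions import (PiecewiseLinearCdf, ScheduleDistributions,
                                    calibrate_fertility_pmf,
                                    draw_desired_children)
from nepalsim.entities import VillageState, Villager
from nepalsim.ledger import Account
from nepalsim.params import ParameterSet
from nepalsim.rng import RngStreams
from nepalsim.scenarios import ScenarioSettings
from nepalsim.synthesis import synthesize_household


def cohort_state(day_index=99, seed=2):
    # day index 99 is day 100 of the year: the education juncture
    return VillageState(clock=SimulationClock(day_index=day_index),
                        params=ParameterSet.defaults(),
                        scenario=ScenarioSettings(), rng=RngStreams(seed))


def make_villager(state, **kw):
    kw.setdefault("sex", "m")
    kw.setdefault("age_days", 30 * DAYS_PER_YEAR)
    kw.setdefault("household_id", 0)
    v = Villager(id=state.new_villager_id(), **kw)
    state.villagers[v.id] = v
    return v


# -- careers ----------------------------------------------------------------

def test_half_of_school_completers_enter_college():
    state = cohort_state()
    n = 10_000
    outcomes = []
    for _ in range(n):
        v = make_villager(state, age_days=SCHOOL_END_AGE_DAYS,
                          education="school", career="student")
        update_career(v, state)
        outcomes.append(v.education)
    frac = outcomes.count("plus2") / n
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n)


def test_quarter_of_college_completers_get_salaried_jobs():
    state = cohort_state()
    n = 10_000
    count = 0
    for _ in range(n):
        v = make_villager(state, age_days=PLUS2_END_AGE_DAYS,
                          education="plus2", career="student")
        update_career(v, state)
        count += v.career == "salaried-1"
    p = 0.25
    assert abs(count / n - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_no_education_transition_off_day_100():
    state = cohort_state(day_index=50)
    v = make_villager(state, age_days=SCHOOL_END_AGE_DAYS, education="school")
    update_career(v, state)
    assert v.education == "school"


# -- fertility scenario pmfs ------------------------------------------------

@pytest.mark.parametrize("rate", [1.6, 2.1])
def test_fertility_pmf_mean_is_exact(rate):
    pmf = calibrate_fertility_pmf(rate)
    assert pmf.sum() == pytest.approx(1.0)
    assert pmf @ np.arange(5) == pytest.approx(rate, abs=0.005)


@pytest.mark.parametrize("rate", [1.6, 2.1])
def test_desired_children_sample_mean(rate):
    rng = np.random.default_rng(17)
    n = 100_000
    draws = np.array([draw_desired_children(rate, rng) for _ in range(n)])
    sd = draws.std(ddof=1)
    assert abs(draws.mean() - rate) < 3 * sd / np.sqrt(n)


def test_desired_children_truncation_floor():
    rng = np.random.default_rng(3)
    assert all(draw_desired_children(1.6, rng, floor=3) >= 3 for _ in range(200))
    assert draw_desired_children(2.1, rng, floor=7) == 7


# -- schedule distributions -------------------------------------------------

def test_piecewise_cdf_is_monotone_and_ends_at_one():
    d = ScheduleDistributions()
    for cdf in [*d.marriage.values(), *d.mortality.values(),
                d.first_birth_delay, d.birth_interval]:
        assert (np.diff(cdf.fs) >= 0).all()
        assert cdf.fs[0] == 0.0 and cdf.fs[-1] == pytest.approx(1.0)


def test_constrained_marriage_draw_respects_child_age():
    # a 24-year-old mother of a 4-year-old married at or before age 20
    d = ScheduleDistributions()
    rng = np.random.default_rng(0)
    for _ in range(300):
        age = d.draw_marriage_age_days("f", rng, max_years=20.0)
        assert age <= 20 * DAYS_PER_YEAR + 1


def test_empty_viable_region_falls_back_to_minimum():
    cdf = PiecewiseLinearCdf([(10.0, 0.0), (20.0, 1.0)])
    assert cdf.sample(np.random.default_rng(0), lo=25.0) == 25.0


def test_mortality_draws_recover_the_cdf():
    d = ScheduleDistributions()
    rng = np.random.default_rng(11)
    draws = np.array([d.draw_death_age_days("m", rng) for _ in range(10_000)])
    stat, p = stats.kstest(draws / DAYS_PER_YEAR, d.mortality["m"].cdf)
    assert p > 0.01


# -- death, marriage, birth -------------------------------------------------

def find_married_couple(state):
    for v in state.villagers.values():
        if v.sex == "m" and v.married and v.partner_id in state.villagers \
                and v.household_id in state.households:
            return v, state.villagers[v.partner_id]
    raise AssertionError("no couple found")


def test_death_charges_funeral_and_widows_partner(fresh_state):
    state = fresh_state
    husband, wife = find_married_couple(state)
    h = state.households[husband.household_id]
    before = [e for e in state.ledger.entries if e.category == "funeral"]
    process_death(husband, state)
    funerals = [e for e in state.ledger.entries
                if e.category == "funeral" and e not in before]
    assert len(funerals) == 1
    assert funerals[0].amount == -200_000
    assert funerals[0].account_id == h.account.id
    assert wife.widowed


def test_pregnant_widow_keeps_imminent_birth(fresh_state):
    state = fresh_state
    husband, wife = find_married_couple(state)
    wife.next_birth_day = state.clock.day_index + 150  # five months away
    process_death(husband, state)
    assert wife.next_birth_day is not None


def test_distant_scheduled_birth_cancelled_on_widowhood(fresh_state):
    state = fresh_state
    husband, wife = find_married_couple(state)
    wife.next_birth_day = state.clock.day_index + 400
    process_death(husband, state)
    assert wife.next_birth_day is None


def test_sole_member_death_removes_household(fresh_state, reference):
    state = fresh_state
    h = synthesize_household(state, "lone-individual", reference)
    v = state.villagers[h.referent_id]
    n_households = len(state.households)
    n_villagers = len(state.villagers)
    process_death(v, state)
    assert h.id not in state.households
    assert len(state.households) == n_households - 1
    assert len(state.villagers) == n_villagers - 1
    assert not any(a.household_id == h.id for a in state.animals.values())


def test_bride_leaves_and_parents_pay_dowry(fresh_state):
    state = fresh_state
    bride = next(v for v in state.villagers.values()
                 if v.sex == "f" and not v.married
                 and v.father_id in state.villagers)
    payer = state.accounts[state.villagers[bride.father_id].controller_id]
    cash_before = payer.cash
    process_marriage(bride, state, state._reference)
    assert bride.id not in state.villagers
    assert payer.cash == pytest.approx(cash_before - 100_000)


def test_groom_with_living_parents_receives_both_gifts(fresh_state):
    state = fresh_state
    groom = next(v for v in state.villagers.values()
                 if v.sex == "m" and not v.married and v.is_adult
                 and not v.in_education
                 and v.father_id in state.villagers)
    mark = len(state.ledger.entries)
    process_marriage(groom, state, state._reference)
    wedding = [e for e in state.ledger.entries[mark:]
               if e.category == "wedding"]
    couple_acc = state.villagers[groom.id].controller_id
    inflow = sum(e.amount for e in wedding if e.account_id == couple_acc)
    assert inflow == pytest.approx(200_000)  # bride side + groom side
    assert state.villagers[groom.partner_id].sex == "f"


def test_newborns_split_sexes_evenly_and_schedule_next_birth(fresh_state):
    state = fresh_state
    mother = next(v for v in state.villagers.values()
                  if v.sex == "f" and v.married and v.partner_id is not None)
    sexes = []
    mother.desired_children = 10_000  # always below desired: next birth set
    for _ in range(2000):
        process_birth(mother, state)
        baby = state.villagers[mother.children_ids[-1]]
        sexes.append(baby.sex)
        assert baby.age_days == 0
        assert baby.death_age_days > 0
        assert mother.next_birth_day is not None
    frac = sexes.count("m") / len(sexes)
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(len(sexes))


def test_mother_at_desired_count_schedules_no_birth(fresh_state):
    state = fresh_state
    mother = next(v for v in state.villagers.values()
                  if v.sex == "f" and v.married and v.partner_id is not None)
    mother.desired_children = len(mother.children_ids) + 1
    process_birth(mother, state)
    assert mother.next_birth_day is None


# -- initialisation rules ---------------------------------------------------

def test_education_initialisation_thresholds():
    state = cohort_state()
    rng = state.rng.demography
    v = make_villager(state, age_days=2000)
    initialize_attainment_for_age(v, state, rng)
    assert v.education == "pre-school"
    v = make_villager(state, age_days=3000)
    initialize_attainment_for_age(v, state, rng)
    assert v.education == "school"


def test_thirty_year_olds_hold_slc_a_quarter_of_the_time():
    state = cohort_state()
    rng = state.rng.demography
    n = 8000
    count = 0
    for _ in range(n):
        v = make_villager(state, age_days=30 * DAYS_PER_YEAR)
        initialize_attainment_for_age(v, state, rng)
        assert v.attainment in ("SLC", "none")
        count += v.attainment == "SLC"
    assert abs(count / n - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)


def test_long_married_childless_women_desire_no_children(init_state):
    for v in init_state.villagers.values():
        if v.sex == "f" and v.married and not v.children_ids \
                and v.marriage_day is not None and v.age_years < 50:
            years_married = -v.marriage_day / DAYS_PER_YEAR
            if years_married > 9.78:
                assert v.desired_children == 0
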