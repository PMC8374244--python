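"""The daily simulation loop.

Each simulated day processes, in a fixed order: villagers (ageing, career,
income, expenses, own-account stock-take, death, marriage, birth), then the
animal classes (chickens, goats, cattle, buffalo), then households (crops,
referent and controller updates, remittance, fission, herd rebalancing,
finance assessment), then polytunnels.  Agents are visited in stable id
order, so a fixed (config, seed) pair reproduces the trajectory bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from .agriculture import (build_yield_models, generate_yield_series,
                          initialize_plantings, process_household_crops,
                          step_polytunnel)
from .clock import SimulationClock, is_month_first_day
from .demography import (initialize_villager_schedules, process_birth,
                         process_death, process_marriage, remove_household,
                         remove_villager, update_career)
from .entities import VillageState
from .finance import (assess_finances, daily_expenses, daily_income,
                      household_fission_check, initialize_finances,
                      settle_field_claims, update_finance_controllers,
                      update_referent, SALARY_PARAM_BY_CAREER)
from .ledger import verify_closure
from .livestock import initialize_household_animals, rebalance_animals, step_animal
from .params import SimulationConfig
from .rng import RngStreams
from .scenarios import EarthquakeTimeline, encode_run_name
from .synthesis import (SynthesisReferenceData, generate_reference_fixture,
                        synthesize_village)

# The reference fixture stands in for one fixed observed dataset, so its
# seed is a constant, not a function of the run seed.
REFERENCE_FIXTURE_SEED = 20150101


@dataclass
class RunResult:
    """Logs and end-of-run summaries for a single simulation."""

    config: SimulationConfig
    summary: dict[str, float]
    events: list[tuple[int, str, str]]
    yield_multipliers: dict[tuple[int, str], float]
    daily_households: list[tuple] = field(default_factory=list)
    daily_villagers: list[tuple] = field(default_factory=list)
    debt_days: int = 0
    ever_in_debt: set[int] = field(default_factory=set)
    households_ever: int = 0
    state: Optional[VillageState] = None

    @property
    def run_name(self) -> str:
        return encode_run_name(self.config.scenario, self.config.seed)


HOUSEHOLD_LOG_COLUMNS = ("day", "household", "members", "fields", "paddy_fields",
                         "polytunnels", "animals", "cash", "debt",
                         "reconstruction_loan", "meat_portions")
VILLAGER_LOG_COLUMNS = ("day", "villager", "household", "sex", "age_days",
                        "education", "career", "controller")


def initialize_state(config: SimulationConfig,
                     ref: SynthesisReferenceData | None = None) -> VillageState:
    """Build the initial village: synthesis, schedules, herds, plantings,
    yields, finances."""
    from .distributions import ScheduleDistributions

    ref = ref or generate_reference_fixture(REFERENCE_FIXTURE_SEED)
    state = VillageState(
        clock=SimulationClock(day_index=0),
        params=config.parameters,
        scenario=config.scenario,
        rng=RngStreams(config.seed),
    )
    state.distributions = ScheduleDistributions()
    state.yield_models = build_yield_models(config.scenario)
    generate_yield_series(state)
    if config.scenario.earthquake and config.invoke_scenario_hooks:
        state.earthquake_timeline = EarthquakeTimeline()
    synthesize_village(state, ref, config.n_households)
    initialize_villager_schedules(state, ref)
    for h in sorted(state.households.values(), key=lambda h: h.id):
        update_referent(state, h)
        update_finance_controllers(state, h)
        initialize_household_animals(state, h)
    initialize_plantings(state)
    initialize_finances(state, ref.household_net_finances)
    for acc in state.accounts.values():
        acc.opening_cash = acc.cash
    state._initial_population = len(state.villagers)
    state._reference = ref
    return state


def apply_earthquake_day(state: VillageState) -> None:
    """Shock-day losses and emigrations, and the later reconstruction
    loans.  A no-op except on the timeline's event days."""
    eq = state.earthquake_timeline
    if eq is None:
        return
    day = state.clock.day_index
    rng = state.rng.scenario
    if day == eq.shock_day:
        for a in sorted(state.animals.values(), key=lambda a: a.id):
            if rng.uniform() < eq.livestock_mortality:
                del state.animals[a.id]  # no sale: markets are cut off
        state.log_event("earthquake", "main shock")
        for h in sorted(state.households.values(), key=lambda h: h.id):
            members = state.household_members(h)
            leave = False
            if len(members) == 1:
                leave = rng.uniform() < eq.emigration_probability
            elif len(members) == 2 and all(v.is_adult for v in members) and \
                    any(v.career in SALARY_PARAM_BY_CAREER for v in members):
                leave = rng.uniform() < eq.emigration_probability
            if leave:
                state.log_event("earthquake-emigration", f"H{h.id}")
                for v in list(members):
                    remove_villager(state, v, death=False)
                remove_household(state, h.id)
    elif day == eq.loan_day:
        for h in sorted(state.households.values(), key=lambda h: h.id):
            amount = eq.reconstruction_loan(len(h.member_ids))
            if amount <= 0:
                continue
            acc = h.account
            acc.reconstruction_loan += amount
            acc.recon_instalment = amount / 60.0
            # the loan is drawn and immediately spent on rebuilding
            state.ledger.post(day, acc, "loan principal", amount)
            state.ledger.post(day, acc, "house construction", -amount)
            state.log_event("reconstruction-loan", f"H{h.id} {amount:.0f}")


def _log_day(state: VillageState, result: RunResult) -> None:
    day = state.clock.day_index
    for hid in sorted(state.households):
        h = state.households[hid]
        result.daily_households.append((
            day, hid, len(h.member_ids), h.total_fields, h.paddy_fields,
            h.polytunnels, len(state.household_animals(h)),
            round(h.account.cash, 2), round(h.account.debt, 2),
            round(h.account.reconstruction_loan, 2), h.account.meat_portions))
    for vid in sorted(state.villagers):
        v = state.villagers[vid]
        result.daily_villagers.append((
            day, vid, v.household_id, v.sex, v.age_days, v.education,
            v.career, v.controller_id))


def step_day(state: VillageState, config: SimulationConfig) -> None:
    """Advance the village by one day (the clock is already on the day)."""
    if config.invoke_scenario_hooks and state.earthquake_timeline is not None:
        apply_earthquake_day(state)

    for vid in sorted(state.villagers):
        v = state.villagers.get(vid)
        if v is None or not v.alive:
            continue
        v.age_days += 1
        update_career(v, state)
        daily_income(v, state)
        daily_expenses(v, state)
        own = state.accounts.get(f"V{vid}")
        if own is not None and v.controller_id == own.id:
            assess_finances(own, state)
        if v.age_days >= v.death_age_days:
            process_death(v, state)
            continue
        if (not v.married and v.marriage_age_days is not None
                and v.age_days >= v.marriage_age_days):
            process_marriage(v, state, state._reference)
            continue
        if (v.sex == "f" and v.next_birth_day is not None
                and state.clock.day_index >= v.next_birth_day
                and v.id in state.villagers):
            process_birth(v, state)

    for species in ("chicken", "goat", "cattle", "buffalo"):
        for aid in sorted(state.animals):
            a = state.animals.get(aid)
            if a is None or a.species != species:
                continue
            if a.household_id not in state.households:
                del state.animals[aid]
                continue
            step_animal(a, state)

    for hid in sorted(state.households):
        h = state.households.get(hid)
        if h is None:
            continue
        process_household_crops(h, state)
        settle_field_claims(h, state)
        update_referent(state, h)
        update_finance_controllers(state, h)
        if h.remittance and is_month_first_day(state.clock.day_index):
            state.ledger.post(state.clock.day_index, h.account, "remittance",
                              state.params.remittance_income)
        household_fission_check(h, state)
        if hid not in state.households:
            continue  # the household dissolved during fission/emigration
        rebalance_animals(h, state)
        assess_finances(h.account, state, household=h)

    for hid in sorted(state.households):
        step_polytunnel(state.households[hid], state)


def run_simulation(config: SimulationConfig,
                   ref: SynthesisReferenceData | None = None,
                   keep_state: bool = True) -> RunResult:
    """Execute a full run and return its logs and summary statistics."""
    from .analysis import summarize_run

    state = initialize_state(config, ref)
    result = RunResult(config=config, summary={}, events=state.events,
                       yield_multipliers=dict(state.yield_multipliers))
    result.households_ever = len(state.households)

    if config.simulation_length_days == 0 and config.log_data:
        _log_day(state, result)

    for day in range(config.simulation_length_days):
        state.clock.day_index = day
        step_day(state, config)
        result.households_ever = max(result.households_ever,
                                     state._next_household_id)
        for h in state.households.values():
            if h.account.debt > 0:
                result.debt_days += 1
                result.ever_in_debt.add(h.id)
        if config.log_data:
            _log_day(state, result)

    verify_closure(state.accounts, state.ledger)
    result.summary = summarize_run(state, result)
    if keep_state:
        result.state = state
    if config.log_data and config.output_path:
        from .runlog import write_run_log
        write_run_log(result, config.output_path)
    return result
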