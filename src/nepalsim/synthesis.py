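"""Initial village generation: household-structured population synthesis.

The village is synthesised household-first: archetypes are drawn for the
requested number of households by stochastic universal sampling, then each
household is populated member-by-member (referent, partner, children,
grandparents, siblings, in-laws as the archetype requires) by resampling
from reference sets of observed ages, age gaps, and birth intervals.
Land, paddy fields, and polytunnels are then allocated.

The original survey reference sets are not published: a seeded fixture
generator (:func:`generate_reference_fixture`) produces a structurally
equivalent stand-in, and every synthesis operation takes the reference data
as an argument so a real dataset can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clock import DAYS_PER_YEAR
from .entities import Household, VillageState, Villager
from .ledger import Account

ARCHETYPES = (
    "lone-individual",
    "lone-couple",
    "nuclear",
    "nuclear-grandmother",
    "nuclear-grandparents",
    "nuclear-daughter-in-law",
    "complex",
)

# Default archetype frequencies.  The surveyed frequencies are available
# only graphically; these are deliberately spread ("uniform-ish") and
# configurable through SynthesisReferenceData.
DEFAULT_ARCHETYPE_PROBS = {
    "lone-individual": 0.07,
    "lone-couple": 0.11,
    "nuclear": 0.30,
    "nuclear-grandmother": 0.14,
    "nuclear-grandparents": 0.14,
    "nuclear-daughter-in-law": 0.10,
    "complex": 0.14,
}
assert abs(sum(DEFAULT_ARCHETYPE_PROBS.values()) - 1.0) < 1e-12


@dataclass
class SynthesisReferenceData:
    """Reference sample sets that drive the population synthesis."""

    archetype_probs: dict[str, float]
    referent_ages_by_type: dict[str, list[float]]      # years
    spouse_age_gaps: list[float]                       # husband minus wife, years
    children_given_partner_age: dict[int, list[int]]
    eldest_child_age_given_partner_age: dict[int, list[float]]
    birth_intervals: list[float]                       # years, non-integer
    referent_mother_age_gaps: list[float]
    mother_father_age_gaps: list[float]
    children_given_mother_age: dict[int, list[int]]
    household_net_finances: list[float]                # NPR, debts negative
    sibling_gap_bound: float = 3.0
    sister_in_law_gaps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.archetype_probs) != set(ARCHETYPES):
            raise ValueError("archetype_probs must cover exactly the seven archetypes")
        if abs(sum(self.archetype_probs.values()) - 1.0) > 1e-9:
            raise ValueError("archetype probabilities must sum to 1")
        for t in ARCHETYPES:
            if not self.referent_ages_by_type.get(t):
                raise ValueError(f"empty referent age set for {t!r}")
        if not self.birth_intervals or min(self.birth_intervals) <= 0:
            raise ValueError("birth intervals must be positive and non-empty")
        if not self.sister_in_law_gaps:
            self.sister_in_law_gaps = list(self.spouse_age_gaps)

    # -- CSV round trip -----------------------------------------------------

    def to_csv_dir(self, path: str | Path) -> None:
        """One CSV per sample set, in a flat documented schema."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"archetype": list(self.archetype_probs),
             "probability": list(self.archetype_probs.values())}
        ).to_csv(path / "archetype_probs.csv", index=False)
        rows = [(t, a) for t, ages in self.referent_ages_by_type.items() for a in ages]
        pd.DataFrame(rows, columns=["archetype", "age"]).to_csv(
            path / "referent_ages.csv", index=False)
        for name in ("spouse_age_gaps", "birth_intervals", "referent_mother_age_gaps",
                     "mother_father_age_gaps", "household_net_finances",
                     "sister_in_law_gaps"):
            pd.DataFrame({"value": getattr(self, name)}).to_csv(
                path / f"{name}.csv", index=False)
        for name in ("children_given_partner_age", "eldest_child_age_given_partner_age",
                     "children_given_mother_age"):
            table = getattr(self, name)
            rows = [(k, v) for k, vals in table.items() for v in vals]
            pd.DataFrame(rows, columns=["conditioning_age", "value"]).to_csv(
                path / f"{name}.csv", index=False)

    @classmethod
    def from_csv_dir(cls, path: str | Path) -> "SynthesisReferenceData":
        path = Path(path)
        probs_df = pd.read_csv(path / "archetype_probs.csv")
        probs = dict(zip(probs_df.archetype, probs_df.probability))
        ages_df = pd.read_csv(path / "referent_ages.csv")
        ref_ages = {t: g.age.tolist() for t, g in ages_df.groupby("archetype")}
        simple = {name: pd.read_csv(path / f"{name}.csv").value.tolist()
                  for name in ("spouse_age_gaps", "birth_intervals",
                               "referent_mother_age_gaps", "mother_father_age_gaps",
                               "household_net_finances", "sister_in_law_gaps")}
        cond = {}
        for name in ("children_given_partner_age", "eldest_child_age_given_partner_age",
                     "children_given_mother_age"):
            df = pd.read_csv(path / f"{name}.csv")
            cond[name] = {int(k): g.value.tolist()
                          for k, g in df.groupby("conditioning_age")}
            if name == "children_given_partner_age" or name == "children_given_mother_age":
                cond[name] = {k: [int(v) for v in vals] for k, vals in cond[name].items()}
        return cls(archetype_probs=probs, referent_ages_by_type=ref_ages,
                   spouse_age_gaps=simple["spouse_age_gaps"],
                   children_given_partner_age=cond["children_given_partner_age"],
                   eldest_child_age_given_partner_age=cond["eldest_child_age_given_partner_age"],
                   birth_intervals=simple["birth_intervals"],
                   referent_mother_age_gaps=simple["referent_mother_age_gaps"],
                   mother_father_age_gaps=simple["mother_father_age_gaps"],
                   children_given_mother_age=cond["children_given_mother_age"],
                   household_net_finances=simple["household_net_finances"],
                   sister_in_law_gaps=simple["sister_in_law_gaps"])


def generate_reference_fixture(seed: int = 0) -> SynthesisReferenceData:
    """A seeded, synthetic stand-in for the unpublished survey reference sets.

    Structural properties mirror what the synthesis requires: adult referent
    ages per archetype, mostly-positive spouse gaps, birth intervals of
    roughly two to four (non-integer) years, parity tables rising with age,
    and net household finances spanning debt and savings.
    """
    rng = np.random.default_rng(seed)
    age_ranges = {
        "lone-individual": (55, 78), "lone-couple": (48, 70), "nuclear": (26, 40),
        "nuclear-grandmother": (28, 42), "nuclear-grandparents": (26, 38),
        "nuclear-daughter-in-law": (22, 32), "complex": (24, 34),
    }
    referent_ages = {t: np.round(rng.uniform(lo, hi, 8), 1).tolist()
                     for t, (lo, hi) in age_ranges.items()}
    spouse_gaps = np.round(rng.normal(3.5, 2.2, 20), 1).tolist()
    birth_intervals = np.round(rng.uniform(1.8, 4.2, 15), 2).tolist()
    children_given_partner_age = {}
    eldest_given_partner_age = {}
    for a in (20, 25, 30, 35, 40, 45):
        lam = min(3.5, 0.8 + a / 14)
        counts = np.clip(rng.poisson(lam, 8), 1 if a >= 25 else 0, 5)
        children_given_partner_age[a] = [int(c) for c in counts]
        eldest = np.clip(np.round(a - 21 + rng.normal(0, 1.5, 6), 1), 0.3, a - 18.5)
        eldest_given_partner_age[a] = eldest.tolist()
    children_given_mother_age = {
        a: [int(c) for c in np.clip(rng.poisson(2.6, 6), 1, 5)]
        for a in (45, 55, 65, 75)
    }
    net_finances = np.round(rng.normal(40000, 150000, 20), -2).tolist()
    return SynthesisReferenceData(
        archetype_probs=dict(DEFAULT_ARCHETYPE_PROBS),
        referent_ages_by_type=referent_ages,
        spouse_age_gaps=spouse_gaps,
        children_given_partner_age=children_given_partner_age,
        eldest_child_age_given_partner_age=eldest_given_partner_age,
        birth_intervals=birth_intervals,
        referent_mother_age_gaps=np.round(rng.uniform(19, 32, 12), 1).tolist(),
        mother_father_age_gaps=np.round(rng.uniform(0, 7, 10), 1).tolist(),
        children_given_mother_age=children_given_mother_age,
        household_net_finances=net_finances,
    )


# --------------------------------------------------------------------------
# Stochastic universal sampling
# --------------------------------------------------------------------------

def sample_household_types(n: int, archetype_probs: dict[str, float],
                           rng: np.random.Generator) -> list[str]:
    """Draw n archetypes by stochastic universal sampling.

    A single uniform offset places n equally spaced pointers on the
    cumulative probability wheel, which guarantees each type's count is
    within one of its expectation n*P(t) while retaining run-to-run
    variability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = list(archetype_probs)
    probs = np.array([archetype_probs[t] for t in labels], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("archetype probabilities must sum to 1")
    cum = np.cumsum(probs)
    start = rng.uniform(0.0, 1.0 / n)
    pointers = start + np.arange(n) / n
    idx = np.searchsorted(cum, pointers, side="right")
    idx = np.minimum(idx, len(labels) - 1)  # guard the 1.0 edge
    return [labels[i] for i in idx]


# --------------------------------------------------------------------------
# Household synthesis
# --------------------------------------------------------------------------

def _years_to_days(years: float) -> int:
    return max(0, int(round(years * DAYS_PER_YEAR)))


def _nearest_key(table: dict[int, list], age: float):
    key = min(table, key=lambda k: abs(k - age))
    return table[key]


def _draw(rng: np.random.Generator, values: list) -> float:
    return values[int(rng.integers(len(values)))]


def _age_noise(rng: np.random.Generator, years: float) -> float:
    """±0.5-year additive uniform noise applied to drawn ages and gaps."""
    return years + rng.uniform(-0.5, 0.5)


def synthesize_household(state: VillageState, archetype: str,
                         ref: SynthesisReferenceData) -> Household:
    """Populate one household of the given archetype, in generation order:
    referent, partner, children, grandmother, grandfather, then the
    archetype-specific siblings or brother + sister-in-law."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = state.rng.synthesis
    hid = state.new_household_id()
    account = Account(id=f"H{hid}")
    state.accounts[account.id] = account
    h = Household(id=hid, archetype=archetype, account=account)
    state.households[hid] = h

    def add(v: Villager) -> Villager:
        state.villagers[v.id] = v
        h.member_ids.append(v.id)
        return v

    # referent: multiplicative ±5% noise; male unless living alone
    ar = _draw(rng, ref.referent_ages_by_type[archetype]) * rng.uniform(0.95, 1.05)
    ref_sex = ("m" if rng.uniform() < 0.5 else "f") if archetype == "lone-individual" else "m"
    referent = add(Villager(id=state.new_villager_id(), sex=ref_sex,
                            age_days=_years_to_days(ar), household_id=hid))
    h.referent_id = referent.id
    if archetype == "lone-individual":
        return h

    # partner: spouse gaps leaving her under 18 are excluded before drawing
    viable_gaps = [g for g in ref.spouse_age_gaps if ar - g >= 18.0]
    gap = _age_noise(rng, _draw(rng, viable_gaps)) if viable_gaps else ar - 18.0
    ap = max(18.0, ar - gap)
    partner = add(Villager(id=state.new_villager_id(), sex="f",
                           age_days=_years_to_days(ap), household_id=hid))
    referent.partner_id, partner.partner_id = partner.id, referent.id
    referent.married = partner.married = True
    lifetime_children = int(_draw(rng, _nearest_key(ref.children_given_partner_age, ap)))
    partner.desired_children = lifetime_children
    if archetype == "lone-couple":
        return h

    if archetype != "nuclear-daughter-in-law":
        _add_children(state, h, referent, partner, ap, lifetime_children, ref, rng)
    if archetype in ("nuclear", "lone-couple"):
        return h
    if archetype == "nuclear-daughter-in-law":
        partner.desired_children = None  # parity handled at schedule initialisation

    if archetype in ("nuclear-grandmother", "nuclear-grandparents",
                     "nuclear-daughter-in-law", "complex"):
        am = _age_noise(rng, ar + _draw(rng, ref.referent_mother_age_gaps))
        mother = add(Villager(id=state.new_villager_id(), sex="f",
                              age_days=_years_to_days(am), household_id=hid))
        referent.mother_id = mother.id
        mother.children_ids.append(referent.id)
        mother.married = True
        if archetype == "nuclear-grandmother":
            mother.widowed = True
            return h

        af = _age_noise(rng, am + _draw(rng, ref.mother_father_age_gaps))
        father = add(Villager(id=state.new_villager_id(), sex="m",
                              age_days=_years_to_days(af), household_id=hid))
        referent.father_id = father.id
        father.children_ids.append(referent.id)
        father.married = True
        mother.partner_id, father.partner_id = father.id, mother.id
        if archetype == "nuclear-grandparents":
            return h

        if archetype == "nuclear-daughter-in-law":
            # referent is the eldest of his siblings; younger siblings live in
            n_siblings = int(_draw(rng, _nearest_key(ref.children_given_mother_age, am)))
            age = ar
            for _ in range(max(0, n_siblings - 1)):
                age -= _draw(rng, ref.birth_intervals)
                if age <= 0:
                    break
                sib = add(Villager(
                    id=state.new_villager_id(),
                    sex="m" if rng.uniform() < 0.5 else "f",
                    age_days=_years_to_days(age), household_id=hid,
                    mother_id=mother.id, father_id=father.id))
                mother.children_ids.append(sib.id)
                father.children_ids.append(sib.id)
            return h

        # complex: referent's brother (age gap under the sibling bound) + wife
        close_gaps = [g for g in ref.birth_intervals if g < ref.sibling_gap_bound]
        bgap = _draw(rng, close_gaps) if close_gaps else ref.sibling_gap_bound / 2
        ab = ar + bgap
        brother = add(Villager(id=state.new_villager_id(), sex="m",
                               age_days=_years_to_days(ab), household_id=hid,
                               mother_id=mother.id, father_id=father.id))
        mother.children_ids.append(brother.id)
        father.children_ids.append(brother.id)
        viable_sil = [g for g in ref.sister_in_law_gaps if ab - g >= 18.0]
        sgap = _age_noise(rng, _draw(rng, viable_sil)) if viable_sil else ab - 18.0
        asil = max(18.0, ab - sgap)
        sil = add(Villager(id=state.new_villager_id(), sex="f",
                           age_days=_years_to_days(asil), household_id=hid))
        brother.partner_id, sil.partner_id = sil.id, brother.id
        brother.married = sil.married = True
    return h


def _add_children(state: VillageState, h: Household, referent: Villager,
                  partner: Villager, ap: float, lifetime_children: int,
                  ref: SynthesisReferenceData, rng: np.random.Generator) -> None:
    """Children of the referent couple; a crossing birth interval becomes the
    provisional date of the next birth."""
    if lifetime_children <= 0:
        return
    # eldest child: redraw values that would imply birth before the mother
    # was a (marriageable) adult
    eldest_ages = _nearest_key(ref.eldest_child_age_given_partner_age, ap)
    ac1 = _draw(rng, eldest_ages)
    for _ in range(50):
        if ac1 <= ap - 18.0:
            break
        ac1 = _draw(rng, eldest_ages)
    else:
        ac1 = max(0.3, ap - 18.0)
    age = ac1
    last_born_age: float | None = None
    for i in range(lifetime_children):
        if i > 0:
            age -= _draw(rng, ref.birth_intervals)
        if age < 0:
            # interval crossed the present: provisional next-birth date
            partner.next_birth_day = _years_to_days(-age)
            break
        child = Villager(id=state.new_villager_id(),
                         sex="m" if rng.uniform() < 0.5 else "f",
                         age_days=_years_to_days(age), household_id=h.id,
                         mother_id=partner.id, father_id=referent.id)
        state.villagers[child.id] = child
        h.member_ids.append(child.id)
        partner.children_ids.append(child.id)
        referent.children_ids.append(child.id)
        last_born_age = age
    if last_born_age is not None:
        # day index of the youngest child's birth, relative to day 0
        partner.last_birth_day = -_years_to_days(last_born_age)


# --------------------------------------------------------------------------
# Land, paddy, polytunnels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandAllocationModel:
    """Regression-based land holdings: ropani as a function of adult count,
    plus two Gaussian noise terms from the regression's error structure."""

    intercept: float = 1.8854
    slope_per_adult: float = 2.0284
    noise1_sd: float = 1.6715
    noise2_sd: float = 0.4728
    floor_ropani: float = 5.0


def allocate_land(h: Household, state: VillageState,
                  model: LandAllocationModel | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Assign the household's land: floored at 5 ropani, in half-ropani
    steps, two fields per ropani."""
    model = model or LandAllocationModel()
    rng = rng if rng is not None else state.rng.synthesis
    a = len(state.adults(h))
    r = (model.intercept + model.slope_per_adult * a
         + rng.normal(0.0, model.noise1_sd) + rng.normal(0.0, model.noise2_sd))
    r = max(model.floor_ropani, round(r * 2.0) / 2.0)
    h.total_fields = int(round(r * 2))
    return r


def allocate_paddy_and_polytunnels(state: VillageState,
                                   rng: np.random.Generator | None = None) -> None:
    """Paddy fields for 16+ ropani holdings; polytunnels for three randomly
    chosen households with at least two adults under 60."""
    rng = rng if rng is not None else state.rng.synthesis
    for h in state.households.values():
        if h.ropani >= 16.0:
            h.paddy_fields = int(rng.integers(2, 5))
    eligible = [h for h in state.households.values()
                if sum(1 for v in state.adults(h) if v.age_years < 60) >= 2]
    chosen_idx = rng.choice(len(eligible), size=min(3, len(eligible)), replace=False) \
        if eligible else []
    for i in np.atleast_1d(chosen_idx):
        eligible[int(i)].polytunnels = int(rng.integers(1, 4))


def synthesize_village(state: VillageState, ref: SynthesisReferenceData,
                       n_households: int = 14) -> None:
    """Full structural synthesis: archetypes, members, land, paddy, tunnels."""
    types = sample_household_types(n_households, ref.archetype_probs,
                                   state.rng.synthesis)
    for t in types:
        synthesize_household(state, t, ref)
    for h in state.households.values():
        allocate_land(h, state)
    allocate_paddy_and_polytunnels(state)
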