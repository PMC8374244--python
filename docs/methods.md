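# Methods note

This note records the model's assumptions, the parameters that matter,
what the synthetic reference data does and does not emulate, the
numerical choices, and the design decisions taken where the printed
record was silent. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Model and schedule

The simulation advances in whole days on a 365-day no-leap calendar
starting 1 Jan 2015 (day 0); the default run is 5,475 days (fifteen
years). Each day executes, in order:

1. **Villagers** (stable id order): age by one day → education/career
   junctures → income → expenses → own-account stock-take (independent
   sons only) → death check → marriage check → birth check. A death and a
   marriage on the same day resolve in favour of the death, so no agent
   acts after dying.
2. **Animals** by class: chickens, goats, cattle, buffalo.
3. **Households**: crop harvest/planting → outstanding fission land
   claims → referent update → finance-controller update → remittance (on
   month firsts) → fission check → herd rebalancing → finance assessment.
4. **Polytunnels**.

Within-day agent order is not specified by the model description; stable
id order was chosen because bit-reproducibility requires *some* fixed
order. One master seed spawns named independent substreams (synthesis,
demography, yields, labour, livestock, scenario, finance) so a change in
one sub-model's draw count cannot perturb the others.

## 2. Money

Every cash movement posts a signed ledger entry against a finance
controller's account; intra-village transfers (wedding gifts, bailouts,
inheritances, fission endowments) post balancing pairs, and flows to the
outside world (markets, employers, dowries leaving with brides) are
single tagged entries. `verify_closure` asserts, after every run, that
each account's cash delta equals its ledger sum — money conservation is
checked, never assumed. Debt is a separate balance: interest accrues on
it daily at `(1.2)^(1/365) − 1`, chosen so unpaid debt grows by exactly
the 20 % annualised informal rate; the reconstruction loan is tracked
separately and accrues no interest.

## 3. Parameters

All empirical constants live in one flat `ParameterSet` (prices, yields,
salaries NPR/month, wages NPR/day, event costs, probabilities); every
value is overridable and the eleven thematic sensitivity groups address
them by name with their default (C) and lower/upper (C−/C+) bounds.
Points needing a decision:

* **Festival cost.** The process description charges NPR 320 per villager
  per festival day; the parameter table prints 200. The default is 320;
  the sensitivity registry carries (200, 160, 240) and the OAT harness
  resets every registered member to its C first, so sensitivity baselines
  use 200. A `table2_festival_preset` switches the default to 200.
* **Animal sale prices.** The parameter table (chicken 1,200; goat 7,600;
  buffalo 28,000/42,000) is the default because it is also the
  sensitivity baseline; the process-text values (1,500; 8,800;
  19,875/26,500) ship as `paper_text_price_preset`.
* **Cattle purchase at NPR 300** in the ownership rules is treated as a
  typo for the tabled 3,000.
* **Festival dates** are never listed, only their count (23) and cost;
  the default calendar spreads 23 days over the main festival clusters
  and is configurable. Only count and cost affect dynamics.

## 4. Distributions available only as curves

Marriage age (by sex), mortality age (by sex, 2015 life-table shape),
first-birth delay, and birth interval are implemented as piecewise-linear
CDFs with implementer-chosen default knots matching the cited curves
qualitatively. Tests therefore target *properties* — monotonicity,
constraint satisfaction under truncated draws, KS-consistency of samples
with the implemented CDF — not the unpublished knot values. The fertility
scenarios are pmfs on {0..4} children built as a convex family anchored
at means of exactly 1.6 and 2.1 with the mass concentrated on one or two
children; `calibrate_fertility_pmf` hits any reachable target mean
exactly because means combine linearly.

The career flow beyond the five printed probabilities (0.5 into +2, 0.25
into salaried work, 0.75/0.5/0.5 for level promotions) is likewise only
available graphically. Defaults: on finishing education men go abroad
with probability 0.30, otherwise labour with probability 0.30, otherwise
farm; women farm; promotions are attempted at ages 30/35/40; salaried
workers in Nepal retire to a pension at 60 and abroad workers return at
60. These are flagged as unverified configuration, not calibrated values.

## 5. Yield model

Annual yield multipliers are `support_max × Beta(α, β)` on [0, 1.25] with
the mode pinned at 1.0, leaving one free concentration parameter that is
solved by bisection (tolerance 1e-6) so that P(m ≤ 0.5) = 1/T for the
scenario's half-yield recurrence interval T ∈ {12, 10, 9, 7} years. The
support bound 1.25 is a design choice (the record fixes only the mode and
the tail mass) and is configurable. Ten years of history plus fifteen
future years are drawn per crop at initialisation, mutually independent
within a year. Forecasts are simple exponential smoothing over the
trailing ten years with α = 0.3 (unspecified; configurable).

Harvest-day values printed above 365 (cabbage 615, cauliflower 419, and
wheat's wrapped 127) are interpreted as growth durations across the year
boundary: a planting's harvest day index is its plant index plus the
(wrap-corrected) growth span. Cabbage therefore stands 396 days, and two
cabbage cohorts briefly coexist; planting is capped by unused fields, and
shortfalls are logged.

The polytunnel calendar — maintenance day 46 (NPR 700), planting day 98
(100 + 770), and fortnightly NPR 4,140 harvests from day 213 to day 44 of
the next year — yields **15** harvests per cycle (213 + 14k, k = 0..14);
the enumeration is asserted in the tests.

## 6. Forecasting ("conservative" made precise)

Controllers forecast a daily balance path 365 days ahead: full (unhalved)
food and living costs, education fees, festivals, meat at the portion
level under consideration, salaries/pensions/remittances on their month
boundaries, labouring at its expected daily rate, herd feed, expected egg
income at the laying duty cycle (30/121), milk at 10/12 of the daily rate
for one/two-member households, crop inputs and harvests at smoothed
multipliers, and polytunnel events. Windfalls — animal trades, gifts,
inheritances — are excluded. Debt repayment is assessed first (pay down
to the forecast minimum balance), then one reconstruction instalment when
otherwise debt-free and affordable for the year, then the largest meat
level (0–3 portions/week, NPR 102 × the age-sex multiplier per dependent,
charged Sundays) that keeps the path non-negative.

Initial cash is the exact amount this forecast requires at two portions a
week ("required cash" can be zero but not negative), plus a historical
net position sampled without replacement from the reference set (negative
draws become opening debt); two households draw a NPR 10,000/month
remittance; independent sons hold savings estimated as years since
completing education × their career's annual net surplus (a constructed
formula — the record gives none). Because the endowment scales with
expenses, short sensitivity runs can show *higher* cash under *higher*
expense parameters; the effect inverts once flows dominate (after about a
year), which is why the direction-sanity test runs two simulated years.

## 7. Synthetic reference data

`generate_reference_fixture` stands in for the unpublished household
survey: archetype frequencies (spread, "uniform-ish"), adult referent age
ranges per archetype, mostly-positive spouse gaps filtered so partners
are ≥ 18, parity tables rising with age, non-integer birth intervals of
roughly 2–4 years, and net finances spanning debt and savings. It
reproduces the *structure* the synthesis needs, not the village's actual
correlations: real kinship networks, wealth-fertility correlations, and
the true archetype mix are not emulated, so passing tests demonstrate
mechanical correctness of the synthesis and dynamics, not demographic
fidelity to any real village. The fixture's seed is fixed (it plays the
role of one observed dataset) and real data in the same CSV schema can be
substituted throughout.

## 8. Numerical conventions and tie-breaks

* Ages are integer days; drawn year-valued ages round to the nearest day.
* Land rounds to the nearest half ropani (one field); fission
  entitlements round half-up to a whole field.
* Cash-crop fields split by largest remainder with ties and leftovers
  favouring potato > cabbage > cauliflower; totals are preserved exactly.
* SUS places n equally spaced pointers after one uniform offset, so each
  archetype's count is within one of n·P(t).
* Gini is half the relative mean absolute difference with negative cash
  clamped at zero (an alternative shift-normalisation was considered and
  rejected as it makes the index depend on the most indebted household).
* Empty truncated-CDF regions fall back to the minimum viable value and
  are logged; overdue initial birth draws resolve on day 1.
* Milk blackouts (two months for cows, three for buffalo, before the next
  birth) only matter for households of size ≤ 2, since larger households
  have no milk surplus to sell.
* Oxen hire (NPR 425/field) is charged at both planting and harvest for
  households without a male bovine, as both process descriptions state.
* Initial plantings standing on 1 Jan 2015 (wheat, cabbage, cauliflower)
  occupy fields but incur no planting cost: those outlays predate the
  window and the initial-cash rule funds the year ahead.

## 9. Problem sizes used in tests and analyses

Distribution-recovery checks use 10⁴–10⁵ draws with three-sigma binomial
tolerances; engine invariants (ledger closure, population bookkeeping,
reproducibility) run on 100–200-day villages; the full-length
(5,475-day) run is exercised once; the sensitivity direction check uses
two-year runs with two replicates per arm under common random numbers.
These sizes were chosen so the whole suite characterises the model in a
few minutes while keeping every tolerance at its statistical meaning.

## 10. Known limitations

* Households do not interact except through kinship transfers; there is
  no land, labour, or credit market between them.
* The career flow's unprinted branches, the distribution knots, the
  stepped ownership tables, and the archetype frequencies are structured
  stand-ins (see §4, §7); conclusions about levels (e.g. absolute debt)
  inherit their uncertainty, while the comparative machinery (scenarios,
  sensitivity groups) is unaffected in design.
* Food and meat prices are fixed; harvests are sold in full and grain
  repurchased at the same price (the sell-all/buy-back simplification).
* The single composite earthquake has no aftershock sequence or
  recurrence; its emigration draws fire once, on the shock day.
* Divorce, remarriage, polygamy, animal disease, and within-village
  breeding chains are absent by design.
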