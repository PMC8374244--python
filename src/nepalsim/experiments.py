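"""Batch experiments: scenario sweeps and grouped one-at-a-time
sensitivity analysis.

A sweep runs every one of the eight scenario combinations a given number
of times; replicate i of a scenario always derives its RNG seed from the
scenario code and i, so re-running a sweep reproduces every output file
byte for byte.

The sensitivity analysis perturbs the eleven thematic parameter groups one
group at a time between their lower (C-) and upper (C+) bounds while all
other parameters sit at their defaults (C), runs a replicate batch per
setting, and reports each summary statistic's percentage change against
the baseline batch together with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd
from scipy.stats import mannwhitneyu

from .analysis import SUMMARY_STATISTICS
from .engine import RunResult, run_simulation
from .params import TABLE7_GROUPS, SimulationConfig
from .scenarios import ScenarioSettings, all_scenario_combinations, encode_run_name

#: shading threshold used when reporting significant sensitivity effects
SIGNIFICANCE_ALPHA = 0.05


def replicate_seed(scenario: ScenarioSettings, replicate: int) -> int:
    """Deterministic, scenario-salted RNG seed for replicate i (< 2^31)."""
    code = encode_run_name(scenario, 0)[:-7]  # e.g. "EQ-21-12"
    return (zlib.crc32(code.encode()) ^ replicate) & 0x7FFFFFFF


def scenario_sweep(base_config: SimulationConfig, n_runs: int,
                   out_dir: str | Path | None = None,
                   progress: Callable[[str], None] | None = None
                   ) -> list[RunResult]:
    """All eight scenario combinations x n_runs replicates.

    Output files (when `out_dir` is given) are named by scenario code and
    replicate index, exactly one file per run.
    """
    results = []
    for scenario in all_scenario_combinations():
        for i in range(1, n_runs + 1):
            cfg = base_config.replace(scenario=scenario, seed=i,
                                      output_path=None)
            # the RNG seed is salted by scenario so replicate i differs
            # across combinations; the filename keeps the replicate index
            rng_cfg = cfg.replace(seed=replicate_seed(scenario, i))
            result = run_simulation(rng_cfg, keep_state=False)
            result.config = cfg  # report under the replicate-index name
            if out_dir is not None and cfg.log_data:
                from .runlog import write_run_log
                write_run_log(result, out_dir)
            if progress is not None:
                progress(result.run_name)
            results.append(result)
    return results


def oat_sensitivity(base_config: SimulationConfig, reps: int,
                    groups: dict[str, dict[str, tuple[float, float, float]]]
                    | None = None,
                    progress: Callable[[str], None] | None = None
                    ) -> pd.DataFrame:
    """Grouped OAT sensitivity analysis.

    Runs `reps` baseline simulations with every registered parameter at its
    C value, then `reps` for each group's C+ and C- settings — with 11
    groups that is reps x (1 + 2 x 11) runs.  Returns a tidy frame with one
    row per (group, direction, statistic): the percentage change of the
    batch mean against baseline, the Mann-Whitney U statistic, its p-value,
    and a significance flag at alpha = 0.05.
    """
    if reps < 2:
        raise ValueError("need at least two replicates per setting")
    groups = TABLE7_GROUPS if groups is None else groups
    for g, members in groups.items():
        unknown = set(members) - set(base_config.parameters)
        if unknown:
            raise KeyError(f"group {g!r} addresses unknown parameters {unknown}")

    def run_batch(params, tag: str) -> pd.DataFrame:
        rows = []
        for i in range(reps):
            cfg = base_config.replace(parameters=params, seed=base_config.seed + i,
                                      log_data=False, output_path=None)
            res = run_simulation(cfg, keep_state=False)
            rows.append(res.summary)
            if progress is not None:
                progress(f"{tag} replicate {i + 1}/{reps}")
        return pd.DataFrame(rows)

    # baseline: every group member at its registered C value
    baseline_params = base_config.parameters.override(
        **{p: c for members in groups.values() for p, (c, _, _) in members.items()})
    baseline = run_batch(baseline_params, "baseline")

    records = []
    for gname, members in groups.items():
        for direction, pick in (("C+", 2), ("C-", 1)):
            params = baseline_params.override(
                **{p: bounds[pick] for p, bounds in members.items()})
            batch = run_batch(params, f"{gname} {direction}")
            for stat in SUMMARY_STATISTICS:
                b, x = baseline[stat], batch[stat]
                base_mean = b.mean()
                pct = float("nan") if base_mean == 0 else \
                    100.0 * (x.mean() - base_mean) / abs(base_mean)
                if b.nunique() == 1 and x.nunique() == 1 and \
                        b.iloc[0] == x.iloc[0]:
                    u, p = reps * reps / 2.0, 1.0
                else:
                    u, p = mannwhitneyu(x, b, alternative="two-sided")
                records.append({
                    "group": gname, "direction": direction, "statistic": stat,
                    "pct_change": pct, "mann_whitney_u": float(u),
                    "p_value": float(p),
                    "significant": bool(p < SIGNIFICANCE_ALPHA),
                })
    return pd.DataFrame.from_records(records)


def planned_run_count(n_groups: int, reps: int) -> int:
    """Total simulations an OAT design schedules: reps x (1 + 2 x groups)."""
    return reps * (1 + 2 * n_groups)
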