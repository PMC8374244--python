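"""Run log files.

One CSV per run, named by the scenario/seed code, with four sections
delimited by marker lines: the scenario header, the annual yield
multipliers, the event log, and the daily agent-state rows (households
then villagers).  The daily household section alone suffices to recompute
every run summary statistic.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path

import pandas as pd

from .engine import HOUSEHOLD_LOG_COLUMNS, RunResult, VILLAGER_LOG_COLUMNS

SECTION_MARKERS = ("# SCENARIO", "# YIELDS", "# EVENTS",
                   "# DAILY_HOUSEHOLDS", "# DAILY_VILLAGERS")


def write_run_log(result: RunResult, path: str | Path) -> Path:
    """Write the run's full log; returns the file path actually written.

    `path` may be a directory (the canonical scenario-coded filename is
    used inside it) or a full file path.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path.mkdir(parents=True, exist_ok=True)
        path = path / result.run_name
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["# SCENARIO"])
    sc = result.config.scenario
    w.writerow(["earthquake", sc.earthquake])
    w.writerow(["fertility_rate", sc.fertility_rate])
    w.writerow(["crop_variability", sc.crop_variability])
    w.writerow(["seed", result.config.seed])
    w.writerow(["simulation_length_days", result.config.simulation_length_days])
    w.writerow(["# YIELDS"])
    w.writerow(["year", "crop", "multiplier"])
    for (year, crop), mult in sorted(result.yield_multipliers.items()):
        w.writerow([year, crop, f"{mult:.6f}"])
    w.writerow(["# EVENTS"])
    w.writerow(["day", "kind", "detail"])
    for day, kind, detail in result.events:
        w.writerow([day, kind, detail])
    w.writerow(["# DAILY_HOUSEHOLDS"])
    w.writerow(HOUSEHOLD_LOG_COLUMNS)
    for row in result.daily_households:
        w.writerow(row)
    w.writerow(["# DAILY_VILLAGERS"])
    w.writerow(VILLAGER_LOG_COLUMNS)
    for row in result.daily_villagers:
        w.writerow(row)
    path.write_text(buf.getvalue())
    return path


def _section_lines(text: str, marker: str) -> list[str]:
    lines = text.splitlines()
    try:
        start = lines.index(marker) + 1
    except ValueError:
        raise ValueError(f"log has no {marker} section") from None
    end = len(lines)
    for i in range(start, len(lines)):
        if lines[i].startswith("# "):
            end = i
            break
    return lines[start:end]


def read_run_log(path: str | Path) -> dict[str, pd.DataFrame | dict]:
    """Parse a run log back into its sections."""
    text = Path(path).read_text()
    scenario = {}
    for line in _section_lines(text, "# SCENARIO"):
        key, value = next(csv.reader([line]))
        scenario[key] = value
    out: dict[str, pd.DataFrame | dict] = {"scenario": scenario}
    for marker, name in (("# YIELDS", "yields"), ("# EVENTS", "events"),
                         ("# DAILY_HOUSEHOLDS", "households"),
                         ("# DAILY_VILLAGERS", "villagers")):
        lines = _section_lines(text, marker)
        if len(lines) <= 1:
            out[name] = pd.DataFrame(columns=next(csv.reader([lines[0]]))
                                     if lines else [])
            continue
        out[name] = pd.read_csv(io.StringIO("\n".join(lines)))
    return out
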