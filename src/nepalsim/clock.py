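"""Simulation calendar.

The simulation starts on 1 January 2015 and advances in whole days on a
365-day no-leap calendar (29 February never occurs; all other month lengths
are Gregorian).  Day index 0 is 1 Jan 2015.  A run of the default length
(5,475 days) therefore spans exactly fifteen years, 2015-2029.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DAYS_PER_YEAR = 365
DEFAULT_SIMULATION_DAYS = 15 * DAYS_PER_YEAR  # 5475

MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

# Cumulative day-of-year at which each month starts (0-based offsets).
_MONTH_STARTS = []
_acc = 0
for _ml in MONTH_LENGTHS:
    _MONTH_STARTS.append(_acc)
    _acc += _ml
assert _acc == DAYS_PER_YEAR

START_YEAR = 2015
# 1 Jan 2015 was a Thursday.  Weekday index: Monday=0 ... Sunday=6.
_START_WEEKDAY = 3

# The village celebrates 23 festival days a year.  The paper gives their
# count and per-day cost but never their dates, so the calendar ships a
# configurable default list of 23 days-of-year loosely following the main
# Nepali festival clusters (Maghe Sankranti, Shivaratri, Holi, Nepali New
# Year, Teej, Dashain, Tihar).  Only the count and cost affect dynamics.
DEFAULT_FESTIVAL_DAYS = frozenset(
    {
        15,  # Maghe Sankranti
        49,  # Shivaratri
        75, 76,  # Holi
        104,  # New Year (Bikram Sambat)
        135,  # Buddha Jayanti
        230, 231,  # Janai Purnima / Gai Jatra
        244, 245, 246,  # Teej
        278, 279, 280, 281, 282,  # Dashain
        307, 308, 309, 310, 311,  # Tihar
        340,  # Yomari Punhi
        355,  # Udhauli
    }
)
assert len(DEFAULT_FESTIVAL_DAYS) == 23


def day_of_year(day_index: int) -> int:
    """Day of the 365-day year, in [1, 365], for a day index (0 = 1 Jan 2015)."""
    if day_index < 0:
        raise ValueError(f"day_index must be >= 0, got {day_index}")
    return day_index % DAYS_PER_YEAR + 1


def calendar_date(day_index: int) -> tuple[int, int, int]:
    """(year, month, day) under the no-leap calendar."""
    doy = day_of_year(day_index) - 1  # 0-based
    year = START_YEAR + day_index // DAYS_PER_YEAR
    month = 12
    for m in range(12):
        if doy < _MONTH_STARTS[m]:
            month = m  # previous month (1-based)
            break
    day = doy - _MONTH_STARTS[month - 1] + 1
    return year, month, day


def day_index_of(year: int, month: int, day: int) -> int:
    """Inverse of :func:`calendar_date`."""
    return (year - START_YEAR) * DAYS_PER_YEAR + _MONTH_STARTS[month - 1] + day - 1


def is_month_first_day(day_index: int) -> bool:
    doy = (day_index % DAYS_PER_YEAR)
    return doy in _MONTH_STARTS


def is_month_last_day(day_index: int) -> bool:
    return is_month_first_day(day_index + 1)


def is_sunday(day_index: int) -> bool:
    return (day_index + _START_WEEKDAY) % 7 == 6


@dataclass
class SimulationClock:
    """Daily clock with the festival calendar attached."""

    day_index: int = 0
    festival_days: frozenset[int] = field(default=DEFAULT_FESTIVAL_DAYS)

    def __post_init__(self) -> None:
        if len(self.festival_days) != 23:
            raise ValueError("festival_days must contain exactly 23 days of the year")

    @property
    def year_day(self) -> int:
        return day_of_year(self.day_index)

    @property
    def calendar_date(self) -> tuple[int, int, int]:
        return calendar_date(self.day_index)

    @property
    def year(self) -> int:
        return START_YEAR + self.day_index // DAYS_PER_YEAR

    @property
    def sim_year(self) -> int:
        """Simulation year index: 0 for 2015, 1 for 2016, ..."""
        return self.day_index // DAYS_PER_YEAR

    def is_festival(self) -> bool:
        return self.year_day in self.festival_days

    def is_sunday(self) -> bool:
        return is_sunday(self.day_index)

    def is_month_first_day(self) -> bool:
        return is_month_first_day(self.day_index)

    def is_month_last_day(self) -> bool:
        return is_month_last_day(self.day_index)

    def tick(self) -> None:
        self.day_index += 1
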