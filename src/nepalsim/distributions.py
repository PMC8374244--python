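"""Schedule distributions for the demographic sub-models.

Marriage-age, mortality-age, first-birth-delay, and birth-interval schedules
are piecewise-linear CDFs.  The published sources behind them (national
demographic surveys, the 2015 WHO life table for Nepal, and a Mid-Hills
fertility study) are available only as curves, so the default knots below
are implementer-chosen to match those shapes qualitatively; every consumer
takes the distribution object as input, so alternative knots can be
substituted without touching the process code.

The two fertility scenarios are probability mass functions over lifetime
children {0..4} constructed to have means of exactly 1.6 and 2.1 children
per woman with the preference mass concentrated on one or two children, as
the focus-group evidence indicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clock import DAYS_PER_YEAR


class PiecewiseLinearCdf:
    """A CDF given by linear interpolation between (x, F(x)) knots.

    Supports inverse-transform sampling, optionally restricted to a viable
    sub-interval [lo, hi] of the support (the restricted CDF is
    renormalised).  If the viable region carries no mass, sampling falls
    back to the minimum viable value.
    """

    def __init__(self, knots: list[tuple[float, float]]) -> None:
        xs = np.array([k[0] for k in knots], dtype=float)
        fs = np.array([k[1] for k in knots], dtype=float)
        if len(xs) < 2 or np.any(np.diff(xs) <= 0):
            raise ValueError("knot x-values must be strictly increasing")
        if fs[0] != 0.0 or abs(fs[-1] - 1.0) > 1e-12 or np.any(np.diff(fs) < 0):
            raise ValueError("knot F-values must rise monotonically from 0 to 1")
        self.xs, self.fs = xs, fs

    @property
    def support(self) -> tuple[float, float]:
        return float(self.xs[0]), float(self.xs[-1])

    def cdf(self, x):
        """F(x); accepts a scalar or an array."""
        return np.interp(x, self.xs, self.fs)

    def quantile(self, u: float) -> float:
        return float(np.interp(u, self.fs, self.xs))

    def sample(self, rng: np.random.Generator,
               lo: float | None = None, hi: float | None = None) -> float:
        f_lo = self.cdf(lo) if lo is not None else 0.0
        f_hi = self.cdf(hi) if hi is not None else 1.0
        if f_hi - f_lo <= 1e-12:
            # empty viable region: fall back to the minimum viable value
            return max(lo if lo is not None else self.xs[0], float(self.xs[0]))
        u = f_lo + rng.uniform() * (f_hi - f_lo)
        return self.quantile(u)


# -- default knots (ages/intervals in years) --------------------------------

MARRIAGE_KNOTS = {
    "f": [(15, 0.0), (17, 0.08), (18, 0.22), (20, 0.50), (22, 0.68),
          (25, 0.85), (28, 0.92), (32, 0.97), (40, 1.0)],
    "m": [(18, 0.0), (20, 0.15), (22, 0.38), (24, 0.58), (27, 0.80),
          (30, 0.90), (35, 0.97), (45, 1.0)],
}

MORTALITY_KNOTS = {
    "m": [(0, 0.0), (1, 0.028), (5, 0.037), (15, 0.043), (30, 0.065),
          (45, 0.115), (55, 0.19), (60, 0.26), (65, 0.36), (70, 0.49),
          (75, 0.64), (80, 0.79), (85, 0.90), (90, 0.965), (95, 0.99),
          (100, 1.0)],
    "f": [(0, 0.0), (1, 0.024), (5, 0.032), (15, 0.038), (30, 0.055),
          (45, 0.095), (55, 0.155), (60, 0.21), (65, 0.30), (70, 0.42),
          (75, 0.57), (80, 0.73), (85, 0.86), (90, 0.95), (95, 0.985),
          (100, 1.0)],
}

FIRST_BIRTH_DELAY_KNOTS = [(0.75, 0.0), (1, 0.18), (1.5, 0.42), (2, 0.60),
                           (2.5, 0.72), (3, 0.80), (4, 0.89), (5, 0.93),
                           (7, 0.97), (10, 1.0)]

BIRTH_INTERVAL_KNOTS = [(1, 0.0), (1.5, 0.10), (2, 0.30), (2.5, 0.50),
                        (3, 0.65), (4, 0.82), (5, 0.90), (7, 0.96), (10, 1.0)]


# -- fertility scenario pmfs ------------------------------------------------

# Anchor pmfs over lifetime children {0,1,2,3,4} with means exactly 1.6 and
# 2.1 and the bulk of the mass on one or two children.
_PMF_LOW = np.array([0.10, 0.36, 0.42, 0.08, 0.04])    # mean 1.60
_PMF_HIGH = np.array([0.05, 0.20, 0.45, 0.20, 0.10])   # mean 2.10
assert abs(_PMF_LOW @ np.arange(5) - 1.6) < 1e-12
assert abs(_PMF_HIGH @ np.arange(5) - 2.1) < 1e-12


def calibrate_fertility_pmf(target_mean: float) -> np.ndarray:
    """A pmf over {0..4} with the requested mean.

    Linear interpolation between the two anchor shapes: means combine
    linearly, so the constraint is met exactly for any target the convex
    family can reach.
    """
    a = (2.1 - target_mean) / 0.5
    pmf = a * _PMF_LOW + (1 - a) * _PMF_HIGH
    if np.any(pmf < 0):
        raise ValueError(f"target mean {target_mean} outside the calibratable range")
    return pmf


def draw_desired_children(fertility_rate: float, rng: np.random.Generator,
                          floor: int = 0) -> int:
    """Lifetime desired children under a fertility scenario, truncated below.

    `floor` is the woman's current child count; the draw never falls below
    it.  With floor beyond the pmf support the floor itself is returned.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    pmf = calibrate_fertility_pmf(fertility_rate)
    if floor >= len(pmf):
        return floor
    tail = pmf[floor:]
    tail = tail / tail.sum()
    return floor + int(rng.choice(len(tail), p=tail))


@dataclass
class ScheduleDistributions:
    """Bundle of the villager life-course schedules used by a run."""

    marriage: dict[str, PiecewiseLinearCdf] = field(default_factory=lambda: {
        s: PiecewiseLinearCdf(k) for s, k in MARRIAGE_KNOTS.items()})
    mortality: dict[str, PiecewiseLinearCdf] = field(default_factory=lambda: {
        s: PiecewiseLinearCdf(k) for s, k in MORTALITY_KNOTS.items()})
    first_birth_delay: PiecewiseLinearCdf = field(
        default_factory=lambda: PiecewiseLinearCdf(FIRST_BIRTH_DELAY_KNOTS))
    birth_interval: PiecewiseLinearCdf = field(
        default_factory=lambda: PiecewiseLinearCdf(BIRTH_INTERVAL_KNOTS))

    # -- draws in days ------------------------------------------------------

    def draw_marriage_age_days(self, sex: str, rng: np.random.Generator,
                               min_years: float | None = None,
                               max_years: float | None = None) -> int:
        years = self.marriage[sex].sample(rng, lo=min_years, hi=max_years)
        return int(round(years * DAYS_PER_YEAR))

    def draw_death_age_days(self, sex: str, rng: np.random.Generator,
                            min_years: float | None = None) -> int:
        years = self.mortality[sex].sample(rng, lo=min_years)
        return max(1, int(round(years * DAYS_PER_YEAR)))

    def draw_first_birth_delay_days(self, rng: np.random.Generator,
                                    min_years: float | None = None) -> int:
        years = self.first_birth_delay.sample(rng, lo=min_years)
        return int(round(years * DAYS_PER_YEAR))

    def draw_birth_interval_days(self, rng: np.random.Generator,
                                 min_years: float | None = None) -> int:
        years = self.birth_interval.sample(rng, lo=min_years)
        return int(round(years * DAYS_PER_YEAR))
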