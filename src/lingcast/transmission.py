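"""Intergenerational-transmission trends (xTFR) and their extrapolation.

The xTFR statistic estimates, from a single age pyramid, the mean number of
children each adult raises in the language:

    xTFR = (10.65 − 12.55 · π_{25−34}) · C / W

with C the number of speakers aged 0–4, W the number aged 15–49 and
π_{25−34} the share of ages 25–34 among the 15–49 group.  Because both
genders are counted, replacement sits near one child speaker per adult
speaker rather than the familiar 2.1 children per woman.

Five historical values (1981, 1986, 1991, 1996, 2001 — the first four via
backward recasting of a 2001 baseline draw) define a trend.  A decreasing
trend is modelled as log-linear in calendar year; a non-decreasing one as
linear in log-year, constrained through an anchor at 2096 equal to the
observed 1981–2001 mean, which keeps extrapolations bounded.  The ``freeze``
scenario evaluates the fitted curve to 2046 and holds it constant
thereafter; ``unlimited`` evaluates it through 2096.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .cohorts_recast import BASELINE_COHORTS, BASELINE_YEAR, recast_backward
from .formats_io import MortalitySchedule, ValidationError

__all__ = [
    "XTFR_INTERCEPT",
    "XTFR_SLOPE",
    "LOG_FLOOR",
    "XTFR_YEARS",
    "PROJECTION_STEP_YEARS",
    "TrendModel",
    "compute_xtfr",
    "xtfr_from_cohort_counts",
    "estimate_xtfr_series",
    "classify_trend",
    "fit_trend",
    "project_xtfr",
    "fit_project_paths",
]

XTFR_INTERCEPT = 10.65
XTFR_SLOPE = 12.55

#: Floor applied before taking logs of xTFR values (half the smallest
#: magnitude the statistic is reported at, 0.01).
LOG_FLOOR = 0.005

#: Years at which historical xTFR values are estimated.
XTFR_YEARS: tuple[int, ...] = (1981, 1986, 1991, 1996, 2001)

#: Years for which projected values are needed (steps 2006–2101 start at 2006…2096).
PROJECTION_STEP_YEARS: tuple[int, ...] = tuple(range(2006, 2097, 5))

FREEZE_YEAR = 2046
ANCHOR_YEAR = 2096


def compute_xtfr(age_counts: Sequence[float], age_los: Sequence[int] | None = None) -> float:
    """Evaluate the xTFR formula on counts by five-year age group.

    ``age_counts`` are ordered by ascending ``age_los`` (default 0, 5, … ).
    Raises when W (ages 15–49) is zero; callers projecting dormant
    populations substitute zero when C is zero too.
    """
    counts = np.asarray(age_counts, dtype=float)
    if age_los is None:
        age_los = np.arange(0, 5 * counts.size, 5)
    age_los = np.asarray(age_los)
    if counts.shape != age_los.shape:
        raise ValidationError("age_counts and age_los must align")
    if (counts < 0).any():
        raise ValidationError("age counts must be non-negative")
    c = float(counts[age_los == 0].sum())
    w_mask = (age_los >= 15) & (age_los <= 45)
    w = float(counts[w_mask].sum())
    if w == 0.0:
        raise ValidationError("xTFR undefined: no speakers aged 15–49")
    pi_mask = (age_los >= 25) & (age_los <= 30)
    pi = float(counts[pi_mask].sum()) / w
    return max(0.0, (XTFR_INTERCEPT - XTFR_SLOPE * pi) * c / w)


def xtfr_from_cohort_counts(cohort_values: Mapping, year: int) -> float:
    """xTFR at ``year`` from counts keyed by :class:`Cohort`.

    Substitutes 0 (with a warning) when no speakers of reproductive age are
    present — the dormant-population convention.
    """
    ages = []
    counts = []
    for cohort, value in cohort_values.items():
        age = cohort.age_lo_at(year)
        if age > 95:
            continue
        ages.append(age)
        counts.append(value)
    try:
        return compute_xtfr(counts, ages)
    except ValidationError:
        warnings.warn(
            f"no speakers aged 15–49 in {year}; substituting xTFR = 0",
            stacklevel=2,
        )
        return 0.0


def estimate_xtfr_series(
    cohort_counts: np.ndarray,
    schedule: MortalitySchedule,
    pop_group: str = "default",
) -> np.ndarray:
    """Historical xTFR values at 1981 … 2001 for one baseline draw.

    ``cohort_counts`` is the draw's 17 cohort counts in birth-year order.
    Years before 2001 use the mortality-free backward recast.
    """
    values = np.zeros(len(XTFR_YEARS))
    for i, year in enumerate(XTFR_YEARS):
        if year == BASELINE_YEAR:
            counts = dict(zip(BASELINE_COHORTS, np.asarray(cohort_counts, dtype=float)))
        else:
            counts = recast_backward(cohort_counts, schedule, year, pop_group)
        values[i] = xtfr_from_cohort_counts(counts, year)
    return values


def classify_trend(values: Sequence[float], years: Sequence[int] = XTFR_YEARS) -> str:
    """"decreasing" iff the least-squares slope of value on year is negative.

    A slope of exactly zero counts as non-decreasing (the mean-anchored
    model is bounded, which makes it the safe branch for flat series).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(years, dtype=float)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return "decreasing" if slope < 0 else "non-decreasing"


@dataclasses.dataclass
class TrendModel:
    """Fitted xTFR time trend.

    ``form`` is "log-response" (decreasing trend: ln value ~ year),
    "log-year" (non-decreasing: value ~ ln year, anchored at 2096) or
    "degenerate" (all-zero series).  Years are centred at 2001 for the
    log-response form; the log-year form uses raw calendar years as printed.
    """

    form: str
    intercept: float
    slope: float
    scenario: str
    anchor_value: float | None = None
    freeze_year: int = FREEZE_YEAR
    anchor_year: int = ANCHOR_YEAR

    def predict(self, years: Sequence[int]) -> np.ndarray:
        yrs = np.asarray(years, dtype=float)
        if self.scenario == "freeze":
            yrs = np.minimum(yrs, self.freeze_year)
        if self.form == "degenerate":
            return np.zeros(yrs.shape)
        if self.form == "log-response":
            return np.exp(self.intercept + self.slope * (yrs - BASELINE_YEAR))
        if self.form == "log-year":
            vals = self.intercept + self.slope * (np.log(yrs) - np.log(self.anchor_year))
            return np.clip(vals, 0.0, None)
        raise ValidationError(f"unknown trend form {self.form!r}")

    def to_json(self) -> str:
        import json

        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def fit_trend(
    values: Sequence[float],
    trend_class: str | None = None,
    scenario: str = "freeze",
    years: Sequence[int] = XTFR_YEARS,
) -> TrendModel:
    """Fit the appropriate trend model to a five-point xTFR series."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(years, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValidationError("need matching year/value series of length >= 2")
    if scenario not in ("freeze", "unlimited"):
        raise ValidationError(f"unknown scenario {scenario!r}")
    if trend_class is None:
        trend_class = classify_trend(y, x)
    if not (y > 0).any():
        return TrendModel(form="degenerate", intercept=0.0, slope=0.0, scenario=scenario)
    if trend_class == "decreasing":
        z = np.log(np.clip(y, LOG_FLOOR, None))
        xc = x - BASELINE_YEAR
        slope = np.sum((xc - xc.mean()) * (z - z.mean())) / np.sum((xc - xc.mean()) ** 2)
        intercept = z.mean() - slope * xc.mean()
        return TrendModel(
            form="log-response", intercept=intercept, slope=slope, scenario=scenario
        )
    # non-decreasing: value ~ ln(year), constrained through (2096, mean value)
    anchor = float(y.mean())
    lx = np.log(x) - np.log(ANCHOR_YEAR)
    slope = float(np.sum(lx * (y - anchor)) / np.sum(lx**2))
    return TrendModel(
        form="log-year",
        intercept=anchor,
        slope=slope,
        scenario=scenario,
        anchor_value=anchor,
    )


def project_xtfr(model: TrendModel, years: Sequence[int] = PROJECTION_STEP_YEARS) -> np.ndarray:
    """Projected xTFR values (floored at 0) at the requested years."""
    return model.predict(years)


def fit_project_paths(
    series: np.ndarray,
    scenario: str = "freeze",
    years: Sequence[int] = PROJECTION_STEP_YEARS,
) -> np.ndarray:
    """Vectorised trend fit + projection for many draws at once.

    ``series`` has shape (n_draws, 5) (values at 1981 … 2001); returns an
    (n_draws, len(years)) array of projected paths.  Semantics match
    :func:`fit_trend` / :func:`project_xtfr` applied row-wise.
    """
    v = np.atleast_2d(np.asarray(series, dtype=float))
    x = np.asarray(XTFR_YEARS, dtype=float)
    yrs = np.asarray(years, dtype=float)
    if scenario == "freeze":
        eval_years = np.minimum(yrs, FREEZE_YEAR)
    else:
        eval_years = yrs

    # decreasing branch: ln value ~ centred year
    xc = x - BASELINE_YEAR
    z = np.log(np.clip(v, LOG_FLOOR, None))
    denom = np.sum((xc - xc.mean()) ** 2)
    b_dec = ((xc - xc.mean()) * (z - z.mean(axis=1, keepdims=True))).sum(axis=1) / denom
    a_dec = z.mean(axis=1) - b_dec * xc.mean()
    path_dec = np.exp(a_dec[:, None] + b_dec[:, None] * (eval_years - BASELINE_YEAR))

    # non-decreasing branch: value ~ ln year through (2096, mean)
    anchor = v.mean(axis=1)
    lx = np.log(x) - np.log(ANCHOR_YEAR)
    b_inc = (lx * (v - anchor[:, None])).sum(axis=1) / np.sum(lx**2)
    path_inc = np.clip(
        anchor[:, None] + b_inc[:, None] * (np.log(eval_years) - np.log(ANCHOR_YEAR)),
        0.0,
        None,
    )

    slope = ((x - x.mean()) * (v - v.mean(axis=1, keepdims=True))).sum(axis=1)
    decreasing = slope < 0
    paths = np.where(decreasing[:, None], path_dec, path_inc)
    paths[~(v > 0).any(axis=1)] = 0.0
    return paths
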