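"""Mortality and fertility machinery for the projector.

Fertility age patterns are summarised by a log-normal density over age:
for a reference year, the age-specific rates for ages 15–49 are normalised
to a profile over the seven group midpoints (17.5 … 47.5) and a log-normal
density (location ``m``, scale ``s`` on log-age) is least-squares fitted to
it.  Patterns for intermediate years come from linear interpolation of
(m, s) between the 2001 and 2100 fits (extrapolated one year to 2101).
The per-period birth-allocation weights — the share of a period's births
attributed to each reproductive age group — are the log-normal density at
the midpoints, renormalised.

Infant survival over the first two-and-a-half years of life is
``(1 − q(0–4))^(1/2)``, the half-interval power under a constant hazard
within the age interval.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable

import numpy as np
from scipy import optimize, stats

from .formats_io import (
    PROJECTION_AGE_LOS,
    REPRODUCTIVE_AGE_LOS,
    FertilityScheduleTable,
    MortalitySchedule,
    ValidationError,
    read_fertility_table,
    read_mortality_schedule,
)

__all__ = [
    "FertilityPattern",
    "BirthAllocationWeights",
    "REPRODUCTIVE_MIDPOINTS",
    "fit_lognormal_pattern",
    "interpolate_pattern",
    "birth_allocation_weights",
    "infant_survival",
    "life_expectancy",
    "weights_by_period",
    "load_default_lifetable",
    "load_default_fertility",
]

#: Age-group midpoints used as density evaluation points.
REPRODUCTIVE_MIDPOINTS = np.asarray(REPRODUCTIVE_AGE_LOS, dtype=float) + 2.5


@dataclasses.dataclass(frozen=True)
class FertilityPattern:
    """Log-normal fertility age pattern for one calendar year.

    ``m`` is the log-normal location (log-years), ``s`` the scale.
    """

    m: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValidationError("log-normal scale must be positive")

    def density(self, ages: np.ndarray) -> np.ndarray:
        return stats.lognorm.pdf(ages, s=self.s, scale=np.exp(self.m))


@dataclasses.dataclass(frozen=True)
class BirthAllocationWeights:
    """Normalised weights over the reproductive age groups 15–19 … 45–49."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.shape != (len(REPRODUCTIVE_AGE_LOS),) or (w < 0).any():
            raise ValidationError("weights must be 7 non-negative values")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights)


def _normalised_profile(rates: np.ndarray) -> np.ndarray:
    total = rates.sum()
    if total <= 0:
        raise ValidationError("fertility rates are all zero; cannot fit a pattern")
    return rates / total


def fit_lognormal_pattern(rates: Iterable[float]) -> FertilityPattern:
    """Least-squares fit of a log-normal age pattern to pooled ASFRs.

    ``rates`` are the seven age-specific rates for 15–19 … 45–49.  Both the
    observed profile and the candidate density are normalised over the
    midpoint grid before comparison, so only the shape matters.
    """
    r = np.asarray(list(rates), dtype=float)
    if r.shape != (len(REPRODUCTIVE_AGE_LOS),):
        raise ValidationError("expected 7 age-specific rates (15–19 … 45–49)")
    if (r < 0).any():
        raise ValidationError("rates must be non-negative")
    profile = _normalised_profile(r)
    mids = REPRODUCTIVE_MIDPOINTS

    def residuals(params: np.ndarray) -> np.ndarray:
        m, log_s = params
        dens = stats.lognorm.pdf(mids, s=np.exp(log_s), scale=np.exp(m))
        total = dens.sum()
        if total <= 0 or not np.isfinite(total):
            return np.full_like(profile, 1e3)
        return dens / total - profile

    mean_age = float((profile * mids).sum())
    x0 = np.array([np.log(mean_age), np.log(0.25)])
    fit = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    m, log_s = fit.x
    return FertilityPattern(m=float(m), s=float(np.exp(log_s)))


def interpolate_pattern(
    p2001: FertilityPattern, p2100: FertilityPattern, year: int
) -> FertilityPattern:
    """Linearly interpolate (m, s) in calendar year between 2001 and 2100.

    Years up to 2101 are allowed (2101 is a one-year extrapolation).
    """
    if not 2001 <= year <= 2101:
        raise ValidationError(f"year {year} outside the 2001–2101 window")
    frac = (year - 2001) / (2100 - 2001)
    m = p2001.m + frac * (p2100.m - p2001.m)
    s = p2001.s + frac * (p2100.s - p2001.s)
    return FertilityPattern(m=m, s=s)


def birth_allocation_weights(pattern: FertilityPattern) -> BirthAllocationWeights:
    """Break a fertility pattern into per-age-group birth shares."""
    dens = pattern.density(REPRODUCTIVE_MIDPOINTS)
    total = dens.sum()
    if total <= 0 or not np.isfinite(total):
        # degenerate s → 0: all mass at the group containing exp(m)
        idx = int(np.argmin(np.abs(np.log(REPRODUCTIVE_MIDPOINTS) - pattern.m)))
        w = np.zeros(len(REPRODUCTIVE_AGE_LOS))
        w[idx] = 1.0
        return BirthAllocationWeights(tuple(w))
    return BirthAllocationWeights(tuple(dens / total))


def weights_by_period(
    fertility: FertilityScheduleTable,
    region: str,
    periods: Iterable[int],
) -> dict[int, BirthAllocationWeights]:
    """Interpolated birth-allocation weights for each requested period."""
    years = fertility.years(region)
    lo, hi = min(years), max(years)
    p_lo = fit_lognormal_pattern(fertility.rates(region, lo))
    p_hi = fit_lognormal_pattern(fertility.rates(region, hi))
    out = {}
    for period in periods:
        year = int(np.clip(period, 2001, 2101))
        out[period] = birth_allocation_weights(interpolate_pattern(p_lo, p_hi, year))
    return out


def infant_survival(schedule: MortalitySchedule, period: int, pop_group: str) -> float:
    """Survival probability over the first 2.5 years of life."""
    q0 = schedule.q(pop_group, period, 0)
    return float(np.sqrt(1.0 - q0))


def life_expectancy(schedule: MortalitySchedule, pop_group: str, period: int) -> float:
    """Period life expectancy at birth from the five-year q ladder.

    Standard closure: survivorship l(x) cumulated from the q's, person-years
    L = 2.5·(l(x) + l(x+5)) per interval, e0 = Σ L / l(0).  The enforced
    q(95–99) = 1 closes the table at age 100.
    """
    q = schedule.q_vector(pop_group, period)
    if np.isnan(q).any():
        raise ValidationError(f"incomplete q ladder for {pop_group} period {period}")
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    person_years = 2.5 * (surv[:-1] + surv[1:])
    return float(person_years.sum())


def load_default_lifetable() -> MortalitySchedule:
    """Synthetic WPP-like life table shipped with the package."""
    with resources.as_file(
        resources.files("lingcast") / "data" / "synthetic_lifetable.csv"
    ) as path:
        return read_mortality_schedule(path)


def load_default_fertility() -> FertilityScheduleTable:
    """Synthetic WPP-like fertility schedule shipped with the package."""
    with resources.as_file(
        resources.files("lingcast") / "data" / "synthetic_fertility.csv"
    ) as path:
        return read_fertility_table(path)
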