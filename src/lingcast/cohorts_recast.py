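"""Birth-cohort bookkeeping and mortality-free recasting of census counts.

A count observed in census year *t* for the five-year age group ``[a, a+4]``
belongs to the birth cohort ``[t − a − 4, t − a]``.  Moving a cohort's count
between observation years uses cumulative survivorship: the count at an
earlier year equals the later count divided by the probability of surviving
the interval, ``N_early = N_late / (1 − M)``, where ``M`` is the cumulative
probability of dying between the two years.  The division form (rather than
a multiplicative "add the deaths" reading) is the only one consistent under
composition of intervals, and is the inverse of binomial survival thinning.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    CENSUS_YEARS,
    OPEN_ENDED_AGE_LO,
    CensusCountTable,
    MortalitySchedule,
    ValidationError,
)

__all__ = [
    "Cohort",
    "BASELINE_COHORTS",
    "RecastEstimates",
    "assign_cohort",
    "cohort_age_lo",
    "cumulative_death_probability",
    "recast_to_2001",
    "recast_backward",
    "survival_factors",
]

BASELINE_YEAR = 2001

#: Oldest age group observable as a closed five-year category.
MAX_CLOSED_AGE_LO = OPEN_ENDED_AGE_LO - 5


@dataclasses.dataclass(frozen=True, order=True)
class Cohort:
    """A five-year birth cohort labelled by inclusive birth years."""

    birth_lo: int

    @property
    def birth_hi(self) -> int:
        return self.birth_lo + 4

    @property
    def label(self) -> str:
        return f"{self.birth_lo}–{self.birth_hi}"

    def age_lo_at(self, year: int) -> int:
        """Lower bound of the cohort's age group in ``year`` (may exceed 95)."""
        age = year - self.birth_hi
        if age < 0:
            raise ValidationError(f"cohort {self.label} not yet born in {year}")
        return age


#: Cohorts 1917–1921 … 1997–2001, the ones observed in all of 2001–2021.
BASELINE_COHORTS: tuple[Cohort, ...] = tuple(
    Cohort(birth_lo) for birth_lo in range(1917, 1998, 5)
)


def assign_cohort(age_lo: int, census_year: int) -> Cohort:
    """Map a closed five-year age group observed at a census to its cohort.

    E.g. ages 0–4 observed in 2001 → cohort 1997–2001; ages 5–9 observed in
    2006 → the same cohort.  The open-ended 100+ group mixes cohorts and is
    not assignable.
    """
    if age_lo >= OPEN_ENDED_AGE_LO:
        raise ValidationError(
            "open-ended 100+ age group cannot be assigned to a single cohort"
        )
    if age_lo < 0 or age_lo % 5:
        raise ValidationError(f"invalid age group lower bound: {age_lo}")
    return Cohort(census_year - age_lo - 4)


def cohort_age_lo(cohort: Cohort, year: int) -> int:
    return cohort.age_lo_at(year)


def cumulative_death_probability(
    cohort: Cohort,
    year_a: int,
    year_b: int,
    schedule: MortalitySchedule,
    pop_group: str,
) -> float:
    """Probability that a cohort member alive in ``year_a`` dies by ``year_b``.

    Computed as ``1 − Π (1 − q(age, period))`` over the five-year steps of
    ``[year_a, year_b)``, with the cohort's age-group label taken at each
    step's start.  Both years must be on the quinquennial grid.
    """
    if (year_b - year_a) % 5 or year_a % 5 != year_b % 5:
        raise ValidationError("years must lie on a common quinquennial grid")
    if year_b < year_a:
        raise ValidationError("year_b must not precede year_a")
    cohort.age_lo_at(year_a)  # raises if not yet born
    surv = 1.0
    for step in range(year_a, year_b, 5):
        age_lo = cohort.age_lo_at(step)
        surv *= 1.0 - schedule.q(pop_group, step, age_lo)
    return 1.0 - surv


def survival_factors(
    cohorts: Sequence[Cohort],
    year_a: int,
    year_b: int,
    schedule: MortalitySchedule,
    pop_group: str,
) -> np.ndarray:
    """Vector of 1 − M(year_a, year_b) per cohort; NaN where not yet born."""
    out = np.full(len(cohorts), np.nan)
    for i, c in enumerate(cohorts):
        if c.birth_hi > year_a:
            continue
        out[i] = 1.0 - cumulative_death_probability(c, year_a, year_b, schedule, pop_group)
    return out


class RecastEstimates:
    """Mortality-free cohort size estimates at a reference year.

    Canonical frame columns: ``language, birth_lo, census_year, estimate``.
    Estimates are real-valued (never re-rounded); one per available
    (language, cohort, census) combination.
    """

    COLUMNS = ("language", "birth_lo", "census_year", "estimate")

    def __init__(self, frame: pd.DataFrame, reference_year: int = BASELINE_YEAR):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"recast estimates: missing columns {missing}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        if (df["estimate"] < 0).any():
            raise ValidationError("recast estimates must be non-negative")
        self.frame = df.sort_values(
            ["language", "birth_lo", "census_year"], kind="mergesort"
        ).reset_index(drop=True)
        self.reference_year = reference_year

    def languages(self) -> list[str]:
        return sorted(self.frame["language"].unique())

    def matrix(self, language: str) -> pd.DataFrame:
        """Cohort (rows, by birth_lo) × census year (columns) estimates."""
        df = self.frame[self.frame["language"] == language]
        if df.empty:
            raise KeyError(language)
        return df.pivot(index="birth_lo", columns="census_year", values="estimate")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def recast_to_2001(
    table: CensusCountTable,
    schedule: MortalitySchedule,
    pop_group: str = "default",
    cohorts: Sequence[Cohort] = BASELINE_COHORTS,
    census_years: Iterable[int] | None = None,
) -> RecastEstimates:
    """Recast observed counts for the baseline cohorts to the year 2001.

    For a census at year t > 2001 the estimate is ``count / (1 − M(2001, t))``
    where M is the cohort's cumulative death probability over [2001, t); the
    2001 census enters unchanged.  Combinations where the cohort has aged
    into the open-ended 100+ category by the census year carry no estimate
    (cohort 1917–1921 in 2021).
    """
    rows = []
    for lang in table.languages():
        years = sorted(census_years) if census_years is not None else table.years(lang)
        for t in years:
            for cohort in cohorts:
                age_lo = t - cohort.birth_hi
                if age_lo < 0 or age_lo > MAX_CLOSED_AGE_LO:
                    continue
                observed = table.count(lang, t, age_lo)
                if t == BASELINE_YEAR:
                    estimate = float(observed)
                else:
                    m = cumulative_death_probability(
                        cohort, BASELINE_YEAR, t, schedule, pop_group
                    )
                    if m >= 1.0:
                        raise ValidationError(
                            f"recast undefined (M=1) for language={lang} "
                            f"cohort={cohort.label} census={t}"
                        )
                    estimate = observed / (1.0 - m)
                rows.append((lang, cohort.birth_lo, t, estimate))
    return RecastEstimates(pd.DataFrame(rows, columns=list(RecastEstimates.COLUMNS)))


def recast_backward(
    baseline_by_cohort: np.ndarray | Sequence[float],
    schedule: MortalitySchedule,
    target_year: int,
    pop_group: str = "default",
    cohorts: Sequence[Cohort] = BASELINE_COHORTS,
) -> dict[Cohort, float]:
    """Recast 2001 cohort counts back to ``target_year`` ∈ {1981, …, 1996}.

    Members who died between the target year and 2001 are restored by
    survivorship inversion: ``N_target = N_2001 / (1 − M(target, 2001))``.
    Cohorts not yet (fully) born at the target year are absent.
    """
    if target_year >= BASELINE_YEAR:
        raise ValidationError("target year must precede the 2001 baseline")
    values = np.asarray(baseline_by_cohort, dtype=float)
    if values.shape != (len(cohorts),):
        raise ValidationError(
            f"expected {len(cohorts)} cohort values, got shape {values.shape}"
        )
    out: dict[Cohort, float] = {}
    for cohort, value in zip(cohorts, values):
        if cohort.birth_hi > target_year:
            continue
        m = cumulative_death_probability(
            cohort, target_year, BASELINE_YEAR, schedule, pop_group
        )
        if m >= 1.0:
            raise ValidationError(
                f"backward recast undefined (M=1) for cohort={cohort.label} "
                f"target={target_year}"
            )
        out[cohort] = value / (1.0 - m)
    return out
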