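"""Individual-based stochastic cohort-component projection, 2001–2101.

Each five-year step applies, to the counts of speakers by five-year age
group, the period's probabilities of dying and of having a child who will
be raised in the language:

* survivors of age group *a* are ``Binomial(count(a), 1 − q(a, period))``
  and move to group *a + 5* (the binomial is the exact aggregate of
  per-individual Bernoulli trials, which is what makes the model
  individual-based); q(95–99) = 1 enforces the maximum age of 100;
* expected births are ``Σ_a count(a) · xTFR_t · weight(a)`` over the
  reproductive groups, realised as a Poisson draw; the entrants to 0–4 are
  the births thinned by the probability of surviving the first two-and-a-
  half years of life.

The ensemble runner redraws, per replicate, a fresh baseline population, a
fresh historical xTFR series and trend fit, and a fresh stochastic
trajectory, using per-replicate random substreams spawned deterministically
from the master seed so any replicate is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from . import transmission
from .baseline import BaselineDraw, BaselineModel, sample_baseline_counts
from .cohorts_recast import BASELINE_COHORTS, BASELINE_YEAR, survival_factors
from .formats_io import (
    PROJECTION_AGE_LOS,
    REPRODUCTIVE_AGE_LOS,
    MortalitySchedule,
    RunConfig,
    ValidationError,
)
from .schedules import BirthAllocationWeights, infant_survival

__all__ = [
    "PopulationState",
    "Trajectory",
    "Ensemble",
    "project_step",
    "run_trajectory",
    "run_ensemble",
]

N_AGES = len(PROJECTION_AGE_LOS)  # 20 groups, 0–4 … 95–99
_REPRO_SLICE = slice(3, 10)  # ages 15–19 … 45–49 within the projection ladder


@dataclasses.dataclass
class PopulationState:
    """Speaker counts by age group 0–4 … 95–99 at one year."""

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_AGES,):
            raise ValidationError(f"state must carry {N_AGES} age groups")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class Trajectory:
    """States at each quinquennial year 2001 … 2101."""

    years: tuple[int, ...]
    counts: np.ndarray  # (n_years, N_AGES)

    def state(self, year: int) -> PopulationState:
        idx = self.years.index(year)
        return PopulationState(year=year, counts=self.counts[idx])

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclasses.dataclass
class Ensemble:
    """Replicate × year × age-group speaker counts for one language."""

    language: str
    years: tuple[int, ...]
    age_los: tuple[int, ...]
    counts: np.ndarray  # (n_reps, n_years, N_AGES)
    master_seed: int | None = None

    @property
    def n_reps(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> np.ndarray:
        """(n_reps, n_years) total speaker counts."""
        return self.counts.sum(axis=2)

    def year_index(self, year: int) -> int:
        return self.years.index(year)


def project_step(
    counts: np.ndarray,
    q_vec: np.ndarray,
    xtfr_t: float,
    weights: np.ndarray | BirthAllocationWeights,
    infant_surv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance one population state by a five-year period."""
    counts = np.asarray(counts, dtype=np.int64)
    if isinstance(weights, BirthAllocationWeights):
        weights = weights.as_array()
    if xtfr_t < 0:
        raise ValidationError("xTFR must be non-negative")
    survivors = rng.binomial(counts, 1.0 - q_vec)
    nxt = np.zeros(N_AGES, dtype=np.int64)
    nxt[1:] = survivors[:-1]  # q(95–99)=1 removes the oldest group
    expected_births = xtfr_t * float(counts[_REPRO_SLICE] @ weights)
    births = rng.poisson(expected_births)
    nxt[0] = rng.binomial(births, infant_surv)
    return nxt


def _draw_to_state(cohort_counts: np.ndarray) -> np.ndarray:
    """Expand 17 cohort counts (birth-year order) to the 20-group ladder."""
    state = np.zeros(N_AGES, dtype=np.int64)
    state[:17] = np.asarray(cohort_counts, dtype=np.int64)[::-1]  # ages 0–84
    return state


def run_trajectory(
    draw: BaselineDraw | np.ndarray,
    xtfr_path: Mapping[int, float],
    schedule: MortalitySchedule,
    rng: np.random.Generator,
    pop_group: str = "default",
    weights: Mapping[int, BirthAllocationWeights] | None = None,
    config: RunConfig | None = None,
) -> Trajectory:
    """Project one baseline draw through 2001–2101.

    ``xtfr_path`` must provide a value for every step year 2001, 2006 … 2096.
    """
    if config is None:
        config = RunConfig()
    years = tuple(config.projection_years)
    cohort_counts = draw.cohort_counts if isinstance(draw, BaselineDraw) else draw
    counts = np.zeros((len(years), N_AGES), dtype=np.int64)
    counts[0] = _draw_to_state(cohort_counts)
    for i, year in enumerate(years[:-1]):
        if year not in xtfr_path:
            raise ValidationError(f"xTFR path missing the {year} step")
        q_vec = schedule.q_vector(pop_group, year)
        w = weights[year].as_array() if weights is not None else _uniform_weights()
        counts[i + 1] = project_step(
            counts[i],
            q_vec,
            float(xtfr_path[year]),
            w,
            infant_survival(schedule, year, pop_group),
            rng,
        )
    return Trajectory(years=years, counts=counts)


def _uniform_weights() -> np.ndarray:
    return np.full(len(REPRODUCTIVE_AGE_LOS), 1.0 / len(REPRODUCTIVE_AGE_LOS))


def run_ensemble(
    model: BaselineModel,
    schedule: MortalitySchedule,
    weights: Mapping[int, BirthAllocationWeights],
    config: RunConfig,
    pop_group: str = "default",
    seed_seq: np.random.SeedSequence | None = None,
) -> Ensemble:
    """Monte-Carlo ensemble for one language.

    Every replicate draws a fresh baseline (total + 17 cohort counts),
    derives a fresh historical xTFR series (2001 directly from the draw,
    1981–1996 via backward recasting), refits and projects the transmission
    trend, and runs a fresh stochastic trajectory.  The 2001–2006 step uses
    the draw's observed 2001 xTFR; projected values serve 2006 onward.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    n_reps = config.n_reps
    years = tuple(config.projection_years)
    step_years = years[:-1]

    # period-level machinery, shared across replicates
    q_mat = np.stack([schedule.q_vector(pop_group, y) for y in step_years])
    if np.isnan(q_mat).any():
        raise ValidationError("mortality schedule does not cover the horizon")
    w_mat = np.stack([weights[y].as_array() for y in step_years])
    isurv = np.array([infant_survival(schedule, y, pop_group) for y in step_years])

    # backward-recast inverse survivorship per historical year, per cohort
    inv_back: dict[int, np.ndarray] = {}
    for y in transmission.XTFR_YEARS[:-1]:
        f = survival_factors(BASELINE_COHORTS, y, BASELINE_YEAR, schedule, pop_group)
        inv_back[y] = 1.0 / f  # NaN where cohort not yet born
    ages_2001 = np.array([BASELINE_YEAR - c.birth_hi for c in BASELINE_COHORTS])

    rngs = [np.random.Generator(np.random.PCG64(s)) for s in seed_seq.spawn(n_reps)]
    draws = np.zeros((n_reps, len(BASELINE_COHORTS)), dtype=np.int64)
    for r in range(n_reps):
        counts, _ = sample_baseline_counts(model, rngs[r], size=1)
        draws[r] = counts[0]

    series = _xtfr_series_batch(draws, inv_back, ages_2001)
    paths = transmission.fit_project_paths(series, scenario=config.scenario)
    path_years = transmission.PROJECTION_STEP_YEARS

    xtfr_by_step = np.zeros((n_reps, len(step_years)))
    xtfr_by_step[:, 0] = series[:, -1]  # observed 2001 value drives 2001–2006
    for j, y in enumerate(step_years[1:], start=1):
        xtfr_by_step[:, j] = paths[:, path_years.index(y)]

    counts = np.zeros((n_reps, len(years), N_AGES), dtype=np.int64)
    for r in range(n_reps):
        rng = rngs[r]
        state = _draw_to_state(draws[r])
        counts[r, 0] = state
        for i in range(len(step_years)):
            state = project_step(
                state, q_mat[i], xtfr_by_step[r, i], w_mat[i], isurv[i], rng
            )
            counts[r, i + 1] = state
    return Ensemble(
        language=model.language,
        years=years,
        age_los=tuple(PROJECTION_AGE_LOS),
        counts=counts,
        master_seed=config.seed,
    )


def _xtfr_series_batch(
    draws: np.ndarray,
    inv_back: Mapping[int, np.ndarray],
    ages_2001: np.ndarray,
) -> np.ndarray:
    """Historical xTFR series for a batch of baseline draws.

    Vectorised equivalent of :func:`transmission.estimate_xtfr_series`
    (replicates where no speaker is of reproductive age get 0).
    """
    n = draws.shape[0]
    years = transmission.XTFR_YEARS
    series = np.zeros((n, len(years)))
    for i, y in enumerate(years):
        if y == BASELINE_YEAR:
            vals = draws.astype(float)
            ages = ages_2001
        else:
            inv = inv_back[y]
            born = ~np.isnan(inv)
            vals = draws[:, born] * inv[born]
            ages = np.array(
                [y - c.birth_hi for c in np.array(BASELINE_COHORTS)[born]]
            )
        c = vals[:, ages == 0].sum(axis=1)
        w_mask = (ages >= 15) & (ages <= 45)
        w = vals[:, w_mask].sum(axis=1)
        pi_mask = (ages >= 25) & (ages <= 30)
        pi = np.divide(
            vals[:, pi_mask].sum(axis=1), w, out=np.zeros(n), where=w > 0
        )
        val = (transmission.XTFR_INTERCEPT - transmission.XTFR_SLOPE * pi) * np.divide(
            c, w, out=np.zeros(n), where=w > 0
        )
        series[:, i] = np.where(w > 0, np.clip(val, 0.0, None), 0.0)
    return series
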