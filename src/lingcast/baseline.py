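"""Probabilistic 2001 baseline populations.

Per language the model separates the error on the total population size from
the error on its age composition:

* the five recast census totals define a t-distribution with location µ
  (their mean), scale τ (the standard error of the mean, sd/√n) and n − 1
  degrees of freedom;
* each of the 17 birth cohorts 1917–1921 … 1997–2001 gets a negative
  binomial distribution with mean µ_c (the cross-census mean of its recast
  estimates) and a quadratic mean–variance relationship,
  variance = φ µ_c² with φ = σ²/µ_c² estimated by moments.  Cohorts whose
  sample variance does not exceed the mean fall back to Poisson; empty
  cohorts are degenerate at zero.

A baseline draw takes one (truncated, rounded) total T from the
t-distribution and 17 cohort counts from their distributions, then rescales
the cohort counts to sum exactly to T using largest-remainder rounding.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .cohorts_recast import BASELINE_COHORTS, BASELINE_YEAR, Cohort, RecastEstimates
from .formats_io import ValidationError
from .quality import ExclusionSet

__all__ = [
    "TotalSizeDistribution",
    "CohortSizeDistribution",
    "BaselineModel",
    "BaselineDraw",
    "fit_total_distribution",
    "fit_cohort_distribution",
    "fit_baseline_model",
    "sample_baseline",
    "sample_baseline_counts",
    "allocate_integer_total",
]


@dataclasses.dataclass(frozen=True)
class TotalSizeDistribution:
    """t-distribution for a language's total 2001 speaker count."""

    mu: float
    tau: float
    df: int

    def __post_init__(self) -> None:
        if self.tau < 0 or self.df < 2:
            raise ValidationError("require tau >= 0 and df >= 2")


@dataclasses.dataclass(frozen=True)
class CohortSizeDistribution:
    """Count distribution for one birth cohort's 2001 size.

    ``phi`` is the dimensionless dispersion, variance / mean².
    """

    mu: float
    phi: float
    family: str  # "negative-binomial" | "poisson" | "degenerate"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValidationError("cohort mean must be non-negative")
        if self.family == "negative-binomial" and self.phi <= 0:
            raise ValidationError("negative binomial requires phi > 0")
        if self.family not in ("negative-binomial", "poisson", "degenerate"):
            raise ValidationError(f"unknown family {self.family!r}")

    @property
    def variance(self) -> float:
        if self.family == "negative-binomial":
            return self.phi * self.mu**2
        if self.family == "poisson":
            return self.mu
        return 0.0


@dataclasses.dataclass
class BaselineModel:
    """Total-size t-distribution plus one count distribution per cohort."""

    language: str
    total: TotalSizeDistribution
    cohorts: dict[Cohort, CohortSizeDistribution]

    def __post_init__(self) -> None:
        if len(self.cohorts) != len(BASELINE_COHORTS):
            raise ValidationError(
                f"expected {len(BASELINE_COHORTS)} cohort distributions, "
                f"got {len(self.cohorts)}"
            )

    def cohort_means(self) -> np.ndarray:
        return np.array([self.cohorts[c].mu for c in BASELINE_COHORTS])

    def to_json(self) -> str:
        payload = {
            "language": self.language,
            "total": dataclasses.asdict(self.total),
            "cohorts": {
                str(c.birth_lo): dataclasses.asdict(d) for c, d in self.cohorts.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BaselineModel":
        payload = json.loads(text)
        return cls(
            language=payload["language"],
            total=TotalSizeDistribution(**payload["total"]),
            cohorts={
                Cohort(int(b)): CohortSizeDistribution(**d)
                for b, d in payload["cohorts"].items()
            },
        )


@dataclasses.dataclass
class BaselineDraw:
    """One sampled 2001 population: counts by age group 0–4 … 80–84."""

    cohort_counts: np.ndarray  # ordered by BASELINE_COHORTS (birth_lo ascending)
    total: int

    def __post_init__(self) -> None:
        if self.cohort_counts.shape != (len(BASELINE_COHORTS),):
            raise ValidationError("baseline draw must carry 17 cohort counts")
        if int(self.cohort_counts.sum()) != self.total:
            raise ValidationError("cohort counts must sum to the realized total")

    @property
    def age_counts(self) -> np.ndarray:
        """Counts by age group 0–4 … 80–84 (ascending age)."""
        # age_lo at 2001 = 2001 − birth_hi, so ascending age = reversed cohorts
        return self.cohort_counts[::-1].copy()

    @property
    def age_los(self) -> np.ndarray:
        return np.arange(0, 85, 5)


def fit_total_distribution(totals: Sequence[float]) -> TotalSizeDistribution:
    """Fit the total-size t-distribution from the recast census totals."""
    x = np.asarray(totals, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 recast totals, got {n}")
    mu = float(x.mean())
    tau = float(x.std(ddof=1) / np.sqrt(n))
    return TotalSizeDistribution(mu=mu, tau=tau, df=n - 1)


def fit_cohort_distribution(estimates: Sequence[float]) -> CohortSizeDistribution:
    """Moment-fit a cohort's count distribution from its recast estimates."""
    x = np.asarray(estimates, dtype=float)
    if (x < 0).any():
        raise ValidationError("cohort estimates must be non-negative")
    mu = float(x.mean())
    if mu == 0.0:
        return CohortSizeDistribution(mu=0.0, phi=0.0, family="degenerate")
    var = float(x.var(ddof=1)) if x.size > 1 else 0.0
    if var <= mu:
        return CohortSizeDistribution(mu=mu, phi=var / mu**2, family="poisson")
    return CohortSizeDistribution(mu=mu, phi=var / mu**2, family="negative-binomial")


def fit_baseline_model(
    recast: RecastEstimates,
    language: str,
    exclusions: ExclusionSet | None = None,
) -> BaselineModel:
    """Fit the full baseline model for one language.

    Census totals flagged by the quality screen are dropped from the
    t-distribution fit; flagged age cells are dropped from the corresponding
    cohort fit.  The (cohort 1917–1921, census 2021) cell is unobservable
    (the cohort has aged into the 100+ category); the census totals impute it
    with the cohort's cross-census mean so the totals stay comparable.
    """
    if exclusions is None:
        exclusions = ExclusionSet()
    mat = recast.matrix(language)  # birth_lo × census_year, NaN where unobservable
    filled = mat.apply(lambda row: row.fillna(row.mean()), axis=1)
    totals = filled.sum(axis=0)
    bad_years = exclusions.excluded_years(language)
    usable = [y for y in totals.index if y not in bad_years]
    total_dist = fit_total_distribution(totals.loc[usable].to_numpy())

    bad_cells = exclusions.excluded_cells(language)
    cohorts: dict[Cohort, CohortSizeDistribution] = {}
    for cohort in BASELINE_COHORTS:
        row = mat.loc[cohort.birth_lo].dropna()
        keep = [y for y in row.index if (cohort.birth_lo, y) not in bad_cells]
        cohorts[cohort] = fit_cohort_distribution(row.loc[keep].to_numpy())
    return BaselineModel(language=language, total=total_dist, cohorts=cohorts)


def allocate_integer_total(weights: np.ndarray, total: int | np.ndarray) -> np.ndarray:
    """Largest-remainder integer allocation of ``total`` proportional to weights.

    Accepts a 1-d weight vector with scalar total, or an (n_draws, k) weight
    matrix with an (n_draws,) total vector.  Rows with zero weight sum raise.
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    t = np.atleast_1d(np.asarray(total, dtype=np.int64))
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    wsum = w.sum(axis=1)
    if ((wsum == 0) & (t > 0)).any():
        raise ValidationError("cannot allocate a positive total over all-zero weights")
    shares = w * np.divide(t, wsum, out=np.zeros_like(wsum), where=wsum > 0)[:, None]
    base = np.floor(shares).astype(np.int64)
    short = t - base.sum(axis=1)
    frac = shares - base
    # stable tie-break: larger remainder first, then lower index
    order = np.argsort(-frac, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1, kind="stable")
    base += ranks < short[:, None]
    if np.ndim(weights) == 1:
        return base[0]
    return base


def sample_baseline_counts(
    model: BaselineModel, rng: np.random.Generator, size: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised baseline sampling.

    Returns ``(cohort_counts, totals)`` with shapes (size, 17) and (size,).
    Draw order is fixed: one batch of t-draws for the totals, then one batch
    per cohort in birth-year order.
    """
    total = model.total
    if total.tau > 0:
        t_draws = total.mu + total.tau * rng.standard_t(total.df, size=size)
    else:
        t_draws = np.full(size, total.mu)
    totals = np.rint(np.clip(t_draws, 0.0, None)).astype(np.int64)

    raw = np.zeros((size, len(BASELINE_COHORTS)), dtype=np.int64)
    for j, cohort in enumerate(BASELINE_COHORTS):
        dist = model.cohorts[cohort]
        if dist.family == "degenerate":
            continue
        if dist.family == "poisson" or dist.variance <= dist.mu:
            raw[:, j] = rng.poisson(dist.mu, size=size)
        else:
            var = dist.variance
            r = dist.mu**2 / (var - dist.mu)  # NB size parameter
            p = r / (r + dist.mu)
            raw[:, j] = rng.negative_binomial(r, p, size=size)

    # rescale to the realized totals with largest-remainder rounding
    weights = raw.astype(float)
    dead_rows = weights.sum(axis=1) == 0
    if dead_rows.any():
        # all-zero cohort draw: redistribute proportionally to cohort means
        means = model.cohort_means()
        if means.sum() == 0:
            means = np.ones_like(means)
        weights[dead_rows] = means
    counts = allocate_integer_total(weights, totals)
    return counts, totals


def sample_baseline(model: BaselineModel, rng: np.random.Generator) -> BaselineDraw:
    """Draw one baseline population realization."""
    counts, totals = sample_baseline_counts(model, rng, size=1)
    return BaselineDraw(cohort_counts=counts[0], total=int(totals[0]))
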