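"""Screening of implausible census observations before baseline fitting.

Two screens run on the mortality-free (recast) estimates:

* **Census totals.**  For each language the five recast totals should agree
  up to sampling noise.  Each total is compared with the mean of the other
  censuses' totals, studentized by their standard deviation with the
  prediction-error factor sqrt(1 + 1/m); the p-value comes from a
  t-distribution with m − 1 degrees of freedom (m = number of reference
  censuses).  Totals with p < 0.001 are excluded from the t-distribution fit.
  The leave-one-out form is essential: with only five observations a gross
  outlier inflates the pooled standard deviation so much that no deviation
  could ever reach p < 0.001 (the pooled |z| is bounded by (n−1)/√n ≈ 1.79).

* **Age cells.**  Within each language, the cohort × census matrix of recast
  estimates is first column-normalised (each census scaled to the mean
  census total) to remove residual whole-census coverage effects, then each
  cell is tested against the other censuses' values for the same cohort with
  the same leave-one-out studentized statistic, at p < 0.01.  Studentizing
  by the cohort's own empirical spread keeps the screen calibrated under
  overdispersed counts, where raw Pearson residuals (variance ≈ 1 + φμ)
  would flag large cohorts wholesale.

Exclusions never reduce a language below three usable censuses, the minimum
for the downstream t-distribution fit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts_recast import RecastEstimates
from .formats_io import ValidationError

__all__ = [
    "ExclusionSet",
    "flag_total_outliers",
    "flag_age_outliers",
    "screen",
    "loo_pvalues",
]

TOTAL_ALPHA = 0.001
CELL_ALPHA = 0.01
MIN_CENSUSES = 3

#: Unbiased random rounding to base 5 has variance E[r(5−r)] = 4 per cell
#: (sd = 2); the studentizing scale is floored there so that deviations the
#: disclosure-control mechanism alone can produce are never flagged.
CELL_SCALE_FLOOR = 2.0
#: Totals sum 17 independently rounded cells: sd = sqrt(17 · 4) ≈ 8.25.
TOTAL_SCALE_FLOOR = float(np.sqrt(17 * 4.0))


@dataclasses.dataclass
class ExclusionSet:
    """Flagged observations with their p-values.

    ``total_exclusions`` maps (language, census_year) → p; these are dropped
    from the total-size fit.  ``cell_exclusions`` maps
    (language, birth_lo, census_year) → p; these are dropped from the
    per-cohort fits.
    """

    total_exclusions: dict[tuple[str, int], float] = dataclasses.field(default_factory=dict)
    cell_exclusions: dict[tuple[str, int, int], float] = dataclasses.field(default_factory=dict)

    def excluded_years(self, language: str) -> set[int]:
        return {y for (lang, y) in self.total_exclusions if lang == language}

    def excluded_cells(self, language: str) -> set[tuple[int, int]]:
        return {
            (b, y) for (lang, b, y) in self.cell_exclusions if lang == language
        }

    def report(self) -> pd.DataFrame:
        rows = [
            {"language": lang, "birth_lo": None, "census_year": year,
             "kind": "total", "p_value": p}
            for (lang, year), p in sorted(self.total_exclusions.items())
        ] + [
            {"language": lang, "birth_lo": b, "census_year": year,
             "kind": "cell", "p_value": p}
            for (lang, b, year), p in sorted(self.cell_exclusions.items())
        ]
        return pd.DataFrame(
            rows, columns=["language", "birth_lo", "census_year", "kind", "p_value"]
        )


def loo_pvalues(values: np.ndarray, min_scale: float = 0.0) -> np.ndarray:
    """Two-sided leave-one-out studentized p-values for a 1-d sample.

    Each value is compared with the mean of the others, scaled by their
    sample standard deviation times sqrt(1 + 1/m); p from t with m − 1 df.
    ``min_scale`` floors the standard deviation (measurement granularity);
    with a zero floor, zero reference spread yields p = 1 for a matching
    value and p = 0 for a deviating one.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < MIN_CENSUSES:
        raise ValidationError(f"need at least {MIN_CENSUSES} values, got {n}")
    p = np.ones(n)
    for i in range(n):
        rest = np.delete(x, i)
        m = rest.size
        mu = rest.mean()
        sd = max(rest.std(ddof=1), min_scale)
        dev = x[i] - mu
        if sd == 0.0:
            p[i] = 1.0 if dev == 0.0 else 0.0
            continue
        t = dev / (sd * np.sqrt(1.0 + 1.0 / m))
        p[i] = 2.0 * stats.t.sf(abs(t), df=m - 1)
    return p


def _totals_by_census(recast: RecastEstimates, language: str) -> pd.Series:
    """Per-census recast totals, imputing unobservable (cohort, census) cells
    with the cohort's cross-census mean so the five totals stay comparable."""
    mat = recast.matrix(language)
    filled = mat.apply(lambda row: row.fillna(row.mean()), axis=1)
    return filled.sum(axis=0)


def flag_total_outliers(recast: RecastEstimates, alpha: float = TOTAL_ALPHA) -> ExclusionSet:
    """Flag (language, census year) whose recast total is implausible."""
    exclusions = ExclusionSet()
    for lang in recast.languages():
        totals = _totals_by_census(recast, lang)
        if totals.size < MIN_CENSUSES:
            continue
        p = loo_pvalues(totals.to_numpy(), min_scale=TOTAL_SCALE_FLOOR)
        flagged = [(y, pv) for y, pv in zip(totals.index, p) if pv < alpha]
        # never drop below the minimum number of usable censuses
        flagged.sort(key=lambda t: t[1])
        keep = max(0, totals.size - MIN_CENSUSES)
        for year, pv in flagged[:keep]:
            exclusions.total_exclusions[(lang, int(year))] = float(pv)
    return exclusions


def flag_age_outliers(recast: RecastEstimates, alpha: float = CELL_ALPHA) -> ExclusionSet:
    """Flag (language, cohort, census year) cells implausible for their cohort."""
    exclusions = ExclusionSet()
    for lang in recast.languages():
        mat = recast.matrix(lang)
        totals = _totals_by_census(recast, lang)
        if totals.size < MIN_CENSUSES:
            continue
        # column-normalise with a robust (median-based) per-census factor so
        # that a single contaminated cell cannot drag its whole census column
        row_med = mat.median(axis=1)
        ratios = mat.div(row_med.replace(0, np.nan), axis=0)
        factors = ratios.median(axis=0).fillna(1.0).replace(0, 1.0)
        norm = mat.div(factors, axis=1)
        for birth_lo, row in norm.iterrows():
            vals = row.dropna()
            if vals.size < MIN_CENSUSES or (vals == 0).all():
                continue
            p = loo_pvalues(vals.to_numpy(), min_scale=CELL_SCALE_FLOOR)
            years = vals.index.to_numpy()
            flagged = sorted(
                ((int(y), float(pv)) for y, pv in zip(years, p) if pv < alpha),
                key=lambda t: t[1],
            )
            keep = max(0, vals.size - MIN_CENSUSES)
            for year, pv in flagged[:keep]:
                exclusions.cell_exclusions[(lang, int(birth_lo), year)] = pv
    return exclusions


def screen(recast: RecastEstimates) -> ExclusionSet:
    """Run both screens and merge the exclusion sets."""
    out = flag_total_outliers(recast)
    out.cell_exclusions.update(flag_age_outliers(recast).cell_exclusions)
    return out
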