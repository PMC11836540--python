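"""Ensemble summaries: medians, 80% projection intervals, dormancy risks.

Quantiles use the inverse-empirical-CDF ("lower") convention on the sorted
integer counts — with small-count languages the quantile convention is
visible in the output, so it is pinned here.  Dormancy risk is the percent
of replicates with zero speakers in an age band (all ages, under 50,
under 15) at a year.  The all-ages and under-50 bands are absorbing (no
speakers under 50 means no future births), so their risks must be
non-decreasing in time and this is asserted; the under-15 band can recover
through new births and is reported unadjusted.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import CensusCountTable, ValidationError
from .projector import Ensemble

__all__ = [
    "BANDS",
    "QUANTILE_METHOD",
    "DormancySummary",
    "summarize_ensemble",
    "dormancy_risk",
    "dormancy_summary",
    "threshold_year",
    "validate_coverage",
    "pooled_coverage",
]

QUANTILE_METHOD = "inverted_cdf"
PI_LO, PI_HI = 0.1, 0.9

#: Age bands: name -> max age-group lower bound included (None = all ages).
BANDS: dict[str, int | None] = {"all": None, "<50": 45, "<15": 10}


def _band_totals(ensemble: Ensemble, band: str) -> np.ndarray:
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}; choose from {list(BANDS)}")
    limit = BANDS[band]
    ages = np.asarray(ensemble.age_los)
    mask = np.ones(ages.size, dtype=bool) if limit is None else ages <= limit
    return ensemble.counts[:, :, mask].sum(axis=2)


def _quantile(values: np.ndarray, q: float, axis: int = 0) -> np.ndarray:
    return np.quantile(values, q, axis=axis, method=QUANTILE_METHOD)


def summarize_ensemble(ensemble: Ensemble) -> pd.DataFrame:
    """Median and 0.1/0.9 quantiles per year, in total and by age group.

    Returns a tidy frame with columns
    ``language, year, age_lo, median, q10, q90`` where ``age_lo`` is -1 for
    the all-age total.
    """
    if ensemble.n_reps < 10:
        raise ValidationError("need at least 10 replicates to summarize")
    rows = []
    totals = ensemble.totals()
    med_t = _quantile(totals, 0.5)
    q10_t = _quantile(totals, PI_LO)
    q90_t = _quantile(totals, PI_HI)
    med_a = _quantile(ensemble.counts, 0.5)
    q10_a = _quantile(ensemble.counts, PI_LO)
    q90_a = _quantile(ensemble.counts, PI_HI)
    for i, year in enumerate(ensemble.years):
        rows.append((ensemble.language, year, -1, med_t[i], q10_t[i], q90_t[i]))
        for j, age_lo in enumerate(ensemble.age_los):
            rows.append(
                (ensemble.language, year, age_lo, med_a[i, j], q10_a[i, j], q90_a[i, j])
            )
    return pd.DataFrame(
        rows, columns=["language", "year", "age_lo", "median", "q10", "q90"]
    )


def dormancy_risk(ensemble: Ensemble, band: str, year: int) -> float:
    """Percent of replicates with zero speakers in the band at the year."""
    totals = _band_totals(ensemble, band)
    idx = ensemble.year_index(year)
    return float(100.0 * (totals[:, idx] == 0).mean())


def threshold_year(
    years: Sequence[int], risks: Sequence[float], threshold: float
) -> int | None:
    """First grid year at which the risk reaches the threshold (≥ rule)."""
    for y, r in zip(years, risks):
        if r >= threshold:
            return int(y)
    return None


@dataclasses.dataclass
class DormancySummary:
    """Dormancy risks per band and year, with 10%/50% threshold years."""

    language: str
    years: tuple[int, ...]
    risks: dict[str, np.ndarray]  # band -> percent per year
    thresholds: dict[str, dict[int, int | None]]  # band -> {10: year, 50: year}

    def table(self) -> pd.DataFrame:
        """Row per band with the 2101-style risk and threshold years."""
        rows = []
        for band in BANDS:
            risk = self.risks[band][-1]
            t10 = self.thresholds[band][10]
            t50 = self.thresholds[band][50]
            rows.append(
                {
                    "language": self.language,
                    "band": band,
                    "risk_final": risk,
                    "year_10pct": "-" if t10 is None else t10,
                    "year_50pct": "-" if t50 is None else t50,
                }
            )
        return pd.DataFrame(rows)


def dormancy_summary(ensemble: Ensemble) -> DormancySummary:
    """Risks for all bands across all years, with internal consistency checks."""
    risks = {}
    for band in BANDS:
        totals = _band_totals(ensemble, band)
        risks[band] = 100.0 * (totals == 0).mean(axis=0)
    # band ordering: the zero events are nested
    if not (
        np.all(risks["all"] <= risks["<50"] + 1e-12)
        and np.all(risks["<50"] <= risks["<15"] + 1e-12)
    ):
        raise AssertionError("band ordering violated: risk(all) ≤ risk(<50) ≤ risk(<15)")
    # absorbing bands must be monotone in time; a violation is an engine bug
    for band in ("all", "<50"):
        if np.any(np.diff(risks[band]) < -1e-12):
            raise AssertionError(f"dormancy risk for band {band!r} decreased over time")
    thresholds = {
        band: {
            10: threshold_year(ensemble.years, risks[band], 10.0),
            50: threshold_year(ensemble.years, risks[band], 50.0),
        }
        for band in BANDS
    }
    return DormancySummary(
        language=ensemble.language,
        years=tuple(ensemble.years),
        risks=risks,
        thresholds=thresholds,
    )


def validate_coverage(
    ensemble: Ensemble,
    observed: CensusCountTable,
    language: str | None = None,
) -> dict:
    """Share of observed census cells inside the 80% projection interval.

    Compares, for every census year covered by the ensemble and every age
    group the engine models (0–4 … 95–99), the observed count with the
    replicate [q10, q90] band.  Returns overall percent plus per-year and
    per-age breakdowns and the cell table.
    """
    language = language or ensemble.language
    years = [y for y in observed.years(language) if y in ensemble.years]
    if not years:
        raise ValidationError("ensemble and observations share no years")
    records = []
    for year in years:
        idx = ensemble.year_index(year)
        cells = ensemble.counts[:, idx, :]
        q10 = _quantile(cells, PI_LO)
        q90 = _quantile(cells, PI_HI)
        for j, age_lo in enumerate(ensemble.age_los):
            obs = observed.count(language, year, age_lo)
            records.append(
                {
                    "language": language,
                    "year": year,
                    "age_lo": age_lo,
                    "observed": obs,
                    "q10": q10[j],
                    "q90": q90[j],
                    "covered": bool(q10[j] <= obs <= q90[j]),
                }
            )
    cells = pd.DataFrame(records)
    return {
        "overall_pct": float(100.0 * cells["covered"].mean()),
        "n_cells": int(len(cells)),
        "by_year": cells.groupby("year")["covered"].mean().mul(100.0).to_dict(),
        "by_age": cells.groupby("age_lo")["covered"].mean().mul(100.0).to_dict(),
        "cells": cells,
    }


def pooled_coverage(reports: Sequence[Mapping]) -> float:
    """Pool per-language coverage reports into one percent over all cells."""
    covered = sum(r["cells"]["covered"].sum() for r in reports)
    n = sum(r["n_cells"] for r in reports)
    if n == 0:
        raise ValidationError("no cells to pool")
    return float(100.0 * covered / n)
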