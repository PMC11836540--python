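"""Tabular input/output, schema validation and run configuration.

All tables travel as comma-separated UTF-8 text with a header row and one
canonical column order per schema:

* speaker counts:      ``language,census_year,age_lo,count``
* life table:          ``pop_group,period_start,age_lo,q5``
* fertility schedule:  ``region,year,age_lo,asfr``

Age groups are encoded by their lower bound (0, 5, …, 100); ``age_lo == 100``
denotes the open-ended "100 years or older" category.  Intervals are
closed-open on the continuous scale but labelled with inclusive integer
endpoints ("0–4", "1997–2001"), matching census publications.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "AgeGroup",
    "CensusCountTable",
    "MortalitySchedule",
    "FertilityScheduleTable",
    "RunConfig",
    "read_census_counts",
    "write_census_counts",
    "read_mortality_schedule",
    "write_mortality_schedule",
    "read_fertility_table",
    "write_fertility_table",
    "load_config",
    "write_manifest",
    "CENSUS_YEARS",
    "CENSUS_AGE_LOS",
    "PROJECTION_AGE_LOS",
    "REPRODUCTIVE_AGE_LOS",
    "OPEN_ENDED_AGE_LO",
]


class SchemaError(Exception):
    """A file does not have the expected columns / coverage."""


class ValidationError(Exception):
    """A table or configuration violates its type invariants."""


#: Census years observed in the source data.
CENSUS_YEARS: tuple[int, ...] = (2001, 2006, 2011, 2016, 2021)

#: Full published age ladder, 0–4 … 95–99 plus the open-ended 100+.
CENSUS_AGE_LOS: tuple[int, ...] = tuple(range(0, 105, 5))

#: Age groups carried by the projection engine (max age at death is 100).
PROJECTION_AGE_LOS: tuple[int, ...] = tuple(range(0, 100, 5))

#: Reproductive age groups 15–19 … 45–49.
REPRODUCTIVE_AGE_LOS: tuple[int, ...] = tuple(range(15, 50, 5))

OPEN_ENDED_AGE_LO: int = 100


@dataclasses.dataclass(frozen=True)
class AgeGroup:
    """A five-year age group, or the open-ended 100+ category."""

    lower: int

    def __post_init__(self) -> None:
        if self.lower % 5 != 0 or not 0 <= self.lower <= OPEN_ENDED_AGE_LO:
            raise ValidationError(f"invalid age-group lower bound: {self.lower}")

    @property
    def open_ended(self) -> bool:
        return self.lower == OPEN_ENDED_AGE_LO

    @property
    def upper(self) -> int | None:
        """Inclusive integer upper label (None for 100+)."""
        return None if self.open_ended else self.lower + 4

    @property
    def label(self) -> str:
        return "100+" if self.open_ended else f"{self.lower}–{self.upper}"

    @property
    def midpoint(self) -> float:
        if self.open_ended:
            raise ValidationError("open-ended age group has no midpoint")
        return self.lower + 2.5


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}; found {list(df.columns)}")


class CensusCountTable:
    """Observed speaker counts keyed by (language, census year, age group).

    Wraps a canonical :class:`pandas.DataFrame` with columns
    ``language, census_year, age_lo, count``.  Every (language, year) pair
    carries the full age ladder 0–4 … 100+.
    """

    COLUMNS = ("language", "census_year", "age_lo", "count")

    def __init__(self, frame: pd.DataFrame, *, rounded_base5: bool = False):
        _require_columns(frame, self.COLUMNS, "census counts")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["census_year"] = df["census_year"].astype(int)
        df["age_lo"] = df["age_lo"].astype(int)
        if df["count"].isna().any():
            raise ValidationError("census counts: NaN count")
        df["count"] = df["count"].astype(int)
        self._validate(df, rounded_base5)
        df = df.sort_values(["language", "census_year", "age_lo"], kind="mergesort")
        self.frame = df.reset_index(drop=True)
        self.rounded_base5 = rounded_base5

    @staticmethod
    def _validate(df: pd.DataFrame, rounded_base5: bool) -> None:
        if (df["count"] < 0).any():
            bad = df[df["count"] < 0].iloc[0]
            raise ValidationError(
                f"negative count for language={bad['language']} "
                f"year={bad['census_year']} age_lo={bad['age_lo']}"
            )
        bad_age = set(df["age_lo"]) - set(CENSUS_AGE_LOS)
        if bad_age:
            raise SchemaError(f"unknown age_lo values: {sorted(bad_age)}")
        ladder = set(CENSUS_AGE_LOS)
        for (lang, year), grp in df.groupby(["language", "census_year"]):
            got = set(grp["age_lo"])
            if got != ladder:
                raise SchemaError(
                    f"language={lang} year={year}: incomplete age ladder, "
                    f"missing {sorted(ladder - got)}"
                )
            if len(grp) != len(ladder):
                raise SchemaError(f"language={lang} year={year}: duplicate age groups")
        if rounded_base5 and (df["count"] % 5 != 0).any():
            raise ValidationError("random-rounding flag set but counts not multiples of 5")

    # -- accessors ---------------------------------------------------------
    def languages(self) -> list[str]:
        return sorted(self.frame["language"].unique())

    def years(self, language: str | None = None) -> list[int]:
        df = self.frame
        if language is not None:
            df = df[df["language"] == language]
        return sorted(df["census_year"].unique())

    def count(self, language: str, year: int, age_lo: int) -> int:
        df = self.frame
        sel = df[
            (df["language"] == language)
            & (df["census_year"] == year)
            & (df["age_lo"] == age_lo)
        ]
        if sel.empty:
            raise KeyError((language, year, age_lo))
        return int(sel["count"].iloc[0])

    def matrix(self, language: str) -> pd.DataFrame:
        """Age (rows) × census year (columns) counts for one language."""
        df = self.frame[self.frame["language"] == language]
        if df.empty:
            raise KeyError(language)
        return df.pivot(index="age_lo", columns="census_year", values="count")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CensusCountTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return (
            f"CensusCountTable({len(self.languages())} languages, "
            f"years {self.years()})"
        )


class MortalitySchedule:
    """Five-year probabilities of dying q(age, period) per population group.

    ``q5`` is the probability of dying within the five-year age interval
    during the five-year period starting at ``period_start``, conditional on
    being alive at the interval's start.  The maximum age at death is 100:
    q is forced to 1 for the 95–99 interval (with a logged warning when the
    input said otherwise).
    """

    COLUMNS = ("pop_group", "period_start", "age_lo", "q5")

    def __init__(self, frame: pd.DataFrame, *, enforce_max_age: bool = True):
        _require_columns(frame, self.COLUMNS, "mortality schedule")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["period_start"] = df["period_start"].astype(int)
        df["age_lo"] = df["age_lo"].astype(int)
        df["q5"] = df["q5"].astype(float)
        if ((df["q5"] < 0) | (df["q5"] > 1)).any() or df["q5"].isna().any():
            raise ValidationError("mortality schedule: q5 outside [0, 1]")
        if enforce_max_age:
            last = df["age_lo"] == 95
            if (df.loc[last, "q5"] < 1).any():
                logger.warning(
                    "q(95-99) < 1 in input; overridden to 1 to enforce max age 100"
                )
                warnings.warn(
                    "q(95-99) overridden to 1 (maximum age at death is 100)",
                    stacklevel=2,
                )
            df.loc[last, "q5"] = 1.0
        df = df.sort_values(["pop_group", "period_start", "age_lo"], kind="mergesort")
        self.frame = df.reset_index(drop=True)
        # dense lookup: group -> {period -> q vector over PROJECTION_AGE_LOS}
        self._lut: dict[str, dict[int, np.ndarray]] = {}
        for (group, period), grp in df.groupby(["pop_group", "period_start"]):
            vec = np.full(len(PROJECTION_AGE_LOS), np.nan)
            idx = (grp["age_lo"].to_numpy() // 5).astype(int)
            ok = idx < len(PROJECTION_AGE_LOS)
            vec[idx[ok]] = grp["q5"].to_numpy()[ok]
            self._lut.setdefault(str(group), {})[int(period)] = vec

    def groups(self) -> list[str]:
        return sorted(self._lut)

    def periods(self, group: str) -> list[int]:
        return sorted(self._lut[group])

    def q(self, group: str, period_start: int, age_lo: int) -> float:
        vec = self.q_vector(group, period_start)
        val = vec[age_lo // 5]
        if np.isnan(val):
            raise SchemaError(
                f"mortality schedule: no q for group={group} "
                f"period={period_start} age_lo={age_lo}"
            )
        return float(val)

    def q_vector(self, group: str, period_start: int) -> np.ndarray:
        """q over the full projection ladder (ages 0–4 … 95–99)."""
        try:
            return self._lut[group][period_start]
        except KeyError:
            raise SchemaError(
                f"mortality schedule: no coverage for group={group} "
                f"period={period_start}"
            ) from None

    def check_coverage(self, group: str, periods: Iterable[int]) -> None:
        for p in periods:
            vec = self.q_vector(group, p)
            if np.isnan(vec).any():
                raise SchemaError(
                    f"mortality schedule: incomplete ages for group={group} period={p}"
                )


class FertilityScheduleTable:
    """Age-specific fertility rates (births per person-year) by region/year."""

    COLUMNS = ("region", "year", "age_lo", "asfr")

    def __init__(self, frame: pd.DataFrame):
        _require_columns(frame, self.COLUMNS, "fertility schedule")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["age_lo"] = df["age_lo"].astype(int)
        df["asfr"] = df["asfr"].astype(float)
        if (df["asfr"] < 0).any() or df["asfr"].isna().any():
            raise ValidationError("fertility schedule: negative or missing asfr")
        expected = set(REPRODUCTIVE_AGE_LOS)
        for (region, year), grp in df.groupby(["region", "year"]):
            if set(grp["age_lo"]) != expected:
                raise SchemaError(
                    f"fertility schedule region={region} year={year}: age groups must "
                    f"cover exactly 15–19 … 45–49"
                )
        df = df.sort_values(["region", "year", "age_lo"], kind="mergesort")
        self.frame = df.reset_index(drop=True)

    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    def years(self, region: str) -> list[int]:
        df = self.frame[self.frame["region"] == region]
        return sorted(df["year"].unique())

    def rates(self, region: str, year: int) -> np.ndarray:
        df = self.frame
        sel = df[(df["region"] == region) & (df["year"] == year)]
        if sel.empty:
            raise KeyError((region, year))
        return sel.sort_values("age_lo")["asfr"].to_numpy()


@dataclasses.dataclass
class RunConfig:
    """Run configuration with the study's default projection calendar."""

    languages: list[str] | None = None
    n_reps: int = 3000
    seed: int = 0
    scenario: str = "freeze"
    baseline_year: int = 2001
    horizon: int = 2101
    freeze_year: int = 2046
    anchor_year: int = 2096
    pop_group: str | Mapping[str, str] = "default"
    region: str = "default"

    def __post_init__(self) -> None:
        if self.n_reps <= 0:
            raise ValidationError("n_reps must be a positive integer")
        if self.scenario not in ("freeze", "unlimited"):
            raise ValidationError(f"unknown scenario: {self.scenario!r}")
        if not (self.baseline_year < self.freeze_year < self.anchor_year < self.horizon):
            raise ValidationError(
                "require baseline_year < freeze_year < anchor_year < horizon, got "
                f"{self.baseline_year} / {self.freeze_year} / "
                f"{self.anchor_year} / {self.horizon}"
            )

    def group_for(self, language: str) -> str:
        if isinstance(self.pop_group, str):
            return self.pop_group
        return self.pop_group.get(language, self.pop_group.get("*", "default"))

    @property
    def projection_years(self) -> list[int]:
        return list(range(self.baseline_year, self.horizon + 1, 5))


# -- readers / writers ------------------------------------------------------

def read_census_counts(path: str | Path, *, rounded_base5: bool = False) -> CensusCountTable:
    """Read a speaker-count table; pads nothing, validates the full ladder."""
    df = _read_csv(path, CensusCountTable.COLUMNS, "census counts")
    return CensusCountTable(df, rounded_base5=rounded_base5)


def write_census_counts(table: CensusCountTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def read_mortality_schedule(path: str | Path, *, enforce_max_age: bool = True) -> MortalitySchedule:
    df = _read_csv(path, MortalitySchedule.COLUMNS, "mortality schedule")
    return MortalitySchedule(df, enforce_max_age=enforce_max_age)


def write_mortality_schedule(schedule: MortalitySchedule, path: str | Path) -> None:
    schedule.frame.to_csv(path, index=False)


def read_fertility_table(path: str | Path) -> FertilityScheduleTable:
    df = _read_csv(path, FertilityScheduleTable.COLUMNS, "fertility schedule")
    return FertilityScheduleTable(df)


def write_fertility_table(table: FertilityScheduleTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def _read_csv(path: str | Path, columns: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # pragma: no cover - malformed text
        raise SchemaError(f"{what}: cannot parse {path}: {exc}") from exc
    _require_columns(df, columns, what)
    return df


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration, filling study defaults.

    An empty or missing document yields the defaults (3000 replicates,
    freeze scenario, 2001 baseline, 2101 horizon).
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise SchemaError("config must be a mapping-style YAML document")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc


def write_manifest(path: str | Path, config: RunConfig, input_paths: Mapping[str, str | Path] | None = None) -> dict:
    """Write a JSON run manifest (seed, config hash, input digests)."""
    import lingcast

    cfg = dataclasses.asdict(config)
    if not isinstance(cfg.get("pop_group"), str):
        cfg["pop_group"] = dict(cfg["pop_group"])
    digests = {}
    for name, p in (input_paths or {}).items():
        digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    manifest = {
        "package": "lingcast",
        "version": lingcast.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": digests,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
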