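"""End-to-end orchestration: counts → screening → baseline → ensemble → tables.

One call runs, per language: cohort recasting to 2001, the quality screens,
the baseline fit, the Monte-Carlo ensemble under the configured scenario,
and the summary/dormancy tables.  Per-language random substreams are
spawned deterministically from the master seed, so results are reproducible
from (inputs, config, seed) alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, quality, schedules
from .baseline import BaselineModel, fit_baseline_model
from .cohorts_recast import RecastEstimates, recast_to_2001
from .formats_io import (
    CensusCountTable,
    FertilityScheduleTable,
    MortalitySchedule,
    RunConfig,
    ValidationError,
    write_manifest,
)
from .projector import Ensemble, run_ensemble
from .quality import ExclusionSet

__all__ = ["LanguageResult", "PipelineResult", "run_pipeline", "save_ensemble", "load_ensemble"]


@dataclasses.dataclass
class LanguageResult:
    language: str
    recast: RecastEstimates
    exclusions: ExclusionSet
    model: BaselineModel
    ensemble: Ensemble
    summary: pd.DataFrame
    dormancy: analysis.DormancySummary


@dataclasses.dataclass
class PipelineResult:
    config: RunConfig
    languages: dict[str, LanguageResult]

    def speaker_table(self) -> pd.DataFrame:
        """Per language: 2001 and final-year medians with 80% intervals."""
        rows = []
        for lang, res in sorted(self.languages.items()):
            s = res.summary
            tot = s[s["age_lo"] == -1].set_index("year")
            first = tot.loc[self.config.baseline_year]
            last = tot.loc[self.config.horizon]
            rows.append(
                {
                    "language": lang,
                    "median_2001": first["median"],
                    "q10_2001": first["q10"],
                    "q90_2001": first["q90"],
                    f"median_{self.config.horizon}": last["median"],
                    f"q10_{self.config.horizon}": last["q10"],
                    f"q90_{self.config.horizon}": last["q90"],
                }
            )
        return pd.DataFrame(rows)

    def dormancy_table(self) -> pd.DataFrame:
        return pd.concat(
            [res.dormancy.table() for _, res in sorted(self.languages.items())],
            ignore_index=True,
        )


def run_pipeline(
    census: CensusCountTable,
    schedule: MortalitySchedule,
    fertility: FertilityScheduleTable,
    config: RunConfig,
) -> PipelineResult:
    """Run the full projection pipeline for the configured languages."""
    langs = config.languages or census.languages()
    missing = set(langs) - set(census.languages())
    if missing:
        raise ValidationError(f"languages not present in the counts: {sorted(missing)}")
    master = np.random.SeedSequence(config.seed)
    lang_seqs = master.spawn(len(langs))
    weights = schedules.weights_by_period(
        fertility, config.region, config.projection_years[:-1]
    )
    results: dict[str, LanguageResult] = {}
    for lang, seq in zip(langs, lang_seqs):
        group = config.group_for(lang)
        sub = CensusCountTable(
            census.frame[census.frame["language"] == lang],
            rounded_base5=census.rounded_base5,
        )
        recast = recast_to_2001(sub, schedule, group)
        exclusions = quality.screen(recast)
        model = fit_baseline_model(recast, lang, exclusions)
        ensemble = run_ensemble(model, schedule, weights, config, group, seq)
        results[lang] = LanguageResult(
            language=lang,
            recast=recast,
            exclusions=exclusions,
            model=model,
            ensemble=ensemble,
            summary=analysis.summarize_ensemble(ensemble),
            dormancy=analysis.dormancy_summary(ensemble),
        )
    return PipelineResult(config=config, languages=results)


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    input_paths: dict | None = None,
    save_ensembles: bool = False,
) -> None:
    """Write summary, dormancy and exclusion tables plus the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.speaker_table().to_csv(out / "speaker_numbers.csv", index=False)
    result.dormancy_table().to_csv(out / "dormancy_risks.csv", index=False)
    pd.concat(
        [res.summary for res in result.languages.values()], ignore_index=True
    ).to_csv(out / "ensemble_summary.csv", index=False)
    reports = [
        r for res in result.languages.values()
        if not (r := res.exclusions.report()).empty
    ]
    if reports:
        excl = pd.concat(reports, ignore_index=True)
    else:
        excl = pd.DataFrame(
            columns=["language", "birth_lo", "census_year", "kind", "p_value"]
        )
    excl.to_csv(out / "exclusions.csv", index=False)
    if save_ensembles:
        for lang, res in result.languages.items():
            save_ensemble(res.ensemble, out / f"ensemble_{lang}.csv.gz")
    write_manifest(out / "manifest.json", result.config, input_paths)


def calibration_experiment(
    seed: int,
    n_reps: int = 3000,
    specs=None,
) -> dict:
    """Self-consistency check of the 80% projection intervals.

    Generates a synthetic census bundle from the named ground-truth
    scenarios (the pipeline's own assumed data-generating process), runs the
    full pipeline, and measures how often the synthetic observed counts fall
    inside the per-cell [q10, q90] bands, pooled over every census year ×
    age-group cell.
    """
    from . import analysis, schedules, synthetic_data

    if specs is None:
        specs = list(synthetic_data.scenario_presets().values())
    schedule = schedules.load_default_lifetable()
    fertility = schedules.load_default_fertility()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    census = synthetic_data.simulate_bundle(specs, schedule, fertility, rng)
    config = RunConfig(n_reps=n_reps, seed=seed)
    result = run_pipeline(census, schedule, fertility, config)
    reports = {
        lang: analysis.validate_coverage(res.ensemble, census)
        for lang, res in result.languages.items()
    }
    return {
        "pooled_pct": analysis.pooled_coverage(list(reports.values())),
        "n_cells": sum(r["n_cells"] for r in reports.values()),
        "per_language_pct": {k: r["overall_pct"] for k, r in reports.items()},
        "result": result,
    }


def save_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Persist replicate × year × age counts as (gzipped) CSV."""
    n_reps, n_years, n_ages = ensemble.counts.shape
    reps = np.repeat(np.arange(n_reps), n_years * n_ages)
    years = np.tile(np.repeat(ensemble.years, n_ages), n_reps)
    ages = np.tile(ensemble.age_los, n_reps * n_years)
    frame = pd.DataFrame(
        {
            "language": ensemble.language,
            "replicate": reps,
            "year": years,
            "age_lo": ages,
            "count": ensemble.counts.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def load_ensemble(path: str | Path) -> Ensemble:
    df = pd.read_csv(path)
    langs = df["language"].unique()
    if len(langs) != 1:
        raise ValidationError("ensemble file must hold exactly one language")
    years = tuple(sorted(df["year"].unique()))
    ages = tuple(sorted(df["age_lo"].unique()))
    reps = sorted(df["replicate"].unique())
    counts = (
        df.sort_values(["replicate", "year", "age_lo"])["count"]
        .to_numpy()
        .reshape(len(reps), len(years), len(ages))
    )
    return Ensemble(
        language=str(langs[0]), years=years, age_los=ages, counts=counts
    )
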