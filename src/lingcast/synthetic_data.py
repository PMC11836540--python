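"""Census-like fixtures generated from known ground truth.

The generator emulates what the pipeline assumes about the data: a closed
population (no migration, no language shift) whose true age structure
evolves by a deterministic expectation recursion under known mortality and
a known transmission (xTFR) trajectory; censuses observe it every five
years from 2001 to 2021 with multiplicative overdispersed count noise
(negative binomial, variance = φ·mean²), optional whole-census undercount
events, and Statistics-Canada-style unbiased random rounding to base 5
(round up with probability remainder/5).

The expectation recursion here doubles as the independent oracle for the
stochastic projector: ensemble means must match it within Monte-Carlo error.

What the generator does *not* emulate: census weighting/imputation
internals, migration, language attrition, and correlated errors between
adjacent censuses.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from . import schedules, transmission
from .formats_io import (
    CENSUS_AGE_LOS,
    CENSUS_YEARS,
    PROJECTION_AGE_LOS,
    CensusCountTable,
    FertilityScheduleTable,
    MortalitySchedule,
    ValidationError,
)

__all__ = [
    "ScenarioSpec",
    "make_true_population",
    "true_xtfr_series",
    "simulate_censuses",
    "random_round_base5",
    "scenario_presets",
    "preset_bundle",
    "make_synthetic_lifetable",
    "make_synthetic_fertility",
    "default_e0_targets",
    "DEFAULT_POP_GROUP",
]

N_AGES = len(PROJECTION_AGE_LOS)
TRUE_YEARS = tuple(range(1981, 2022, 5))
DEFAULT_POP_GROUP = "default"


@dataclasses.dataclass
class ScenarioSpec:
    """Ground truth for one synthetic language.

    ``initial_1981`` is the true population by age group 0–4 … 95–99 in
    1981; ``xtfr_1981_2001`` the true transmission values at the five grid
    years (the post-2001 path is extended with the pipeline's own trend
    model, freeze form, so that synthetic data follow the model's assumed
    dynamics); ``phi_true`` the census overdispersion (variance ÷ mean²);
    ``undercount`` maps census years to multiplicative coverage factors.
    """

    language: str
    initial_1981: np.ndarray
    xtfr_1981_2001: tuple[float, float, float, float, float]
    phi_true: float = 0.005
    undercount: Mapping[int, float] = dataclasses.field(default_factory=dict)
    random_round: bool = True
    noise: str = "nb"  # "nb" | "poisson" (misspecification switch)
    pop_group: str = DEFAULT_POP_GROUP
    region: str = "default"

    def __post_init__(self) -> None:
        self.initial_1981 = np.asarray(self.initial_1981, dtype=float)
        if self.initial_1981.shape != (N_AGES,):
            raise ValidationError(f"initial_1981 must have {N_AGES} age groups")
        if (self.initial_1981 < 0).any():
            raise ValidationError("initial population must be non-negative")
        if self.phi_true <= 0:
            raise ValidationError("phi_true must be positive")
        if any(not 0 < f <= 2 for f in self.undercount.values()):
            raise ValidationError("undercount factors must lie in (0, 2]")
        if self.noise not in ("nb", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")


def _expected_step(
    state: np.ndarray,
    q_vec: np.ndarray,
    xtfr_t: float,
    weights: np.ndarray,
    infant_surv: float,
) -> np.ndarray:
    """Deterministic expectation recursion for one five-year step."""
    nxt = np.zeros_like(state)
    nxt[1:] = state[:-1] * (1.0 - q_vec[:-1])
    repro = state[3:10]  # ages 15–49
    births = xtfr_t * float(repro @ weights)
    nxt[0] = births * infant_surv
    return nxt


def make_true_population(
    spec: ScenarioSpec,
    schedule: MortalitySchedule,
    fertility: FertilityScheduleTable,
) -> dict[int, np.ndarray]:
    """True (real-valued) population by age group for 1981 … 2021.

    Steps 1981–1996 are driven by the spec's transmission values; the 2001
    step uses the 2001 value; steps 2006–2016 use the pipeline's freeze-form
    trend extension of the series measured on the noise-free population.
    """
    periods = range(TRUE_YEARS[0], TRUE_YEARS[-1], 5)
    weights = schedules.weights_by_period(fertility, spec.region, periods)
    states: dict[int, np.ndarray] = {TRUE_YEARS[0]: spec.initial_1981.copy()}
    xtfr_grid = dict(zip(transmission.XTFR_YEARS, spec.xtfr_1981_2001))
    future_path: dict[int, float] | None = None
    for year in periods:
        if year <= 1996:
            xtfr_t = xtfr_grid[year]
        elif year == 2001:
            xtfr_t = xtfr_grid[2001]
        else:
            if future_path is None:
                series = true_xtfr_series(spec, schedule, fertility, states=states)
                model = transmission.fit_trend(series, scenario="freeze")
                proj = transmission.project_xtfr(model)
                future_path = dict(zip(transmission.PROJECTION_STEP_YEARS, proj))
            xtfr_t = future_path[year]
        states[year + 5] = _expected_step(
            states[year],
            schedule.q_vector(spec.pop_group, year),
            float(xtfr_t),
            weights[year].as_array(),
            schedules.infant_survival(schedule, year, spec.pop_group),
        )
    return states


def true_xtfr_series(
    spec: ScenarioSpec,
    schedule: MortalitySchedule,
    fertility: FertilityScheduleTable,
    states: Mapping[int, np.ndarray] | None = None,
) -> np.ndarray:
    """The xTFR functional evaluated on the noise-free population, 1981–2001.

    This is the parameter-recovery target: it isolates measurement and
    recast error from the xTFR formula's own demographic approximation.
    """
    if states is None:
        states = make_true_population(spec, schedule, fertility)
    out = np.zeros(len(transmission.XTFR_YEARS))
    for i, year in enumerate(transmission.XTFR_YEARS):
        counts = states[year]
        try:
            out[i] = transmission.compute_xtfr(counts, np.asarray(PROJECTION_AGE_LOS))
        except ValidationError:
            out[i] = 0.0
    return out


def random_round_base5(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unbiased random rounding to base 5 (round up w.p. remainder/5)."""
    x = np.asarray(values, dtype=np.int64)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    rem = x % 5
    up = rng.random(x.shape) < rem / 5.0
    return x - rem + 5 * up.astype(np.int64)


def _noisy_counts(
    means: np.ndarray, phi: float, noise: str, rng: np.random.Generator
) -> np.ndarray:
    m = np.asarray(means, dtype=float)
    out = np.zeros(m.shape, dtype=np.int64)
    pos = m > 0
    if noise == "poisson":
        out[pos] = rng.poisson(m[pos])
        return out
    var = phi * m**2
    nb = pos & (var > m)
    po = pos & ~nb
    if nb.any():
        r = m[nb] ** 2 / (var[nb] - m[nb])
        out[nb] = rng.negative_binomial(r, r / (r + m[nb]))
    if po.any():
        out[po] = rng.poisson(m[po])
    return out


def simulate_censuses(
    true_pops: Mapping[int, np.ndarray],
    spec: ScenarioSpec,
    rng: np.random.Generator,
    census_years: Sequence[int] = CENSUS_YEARS,
) -> CensusCountTable:
    """Observe the true population with census noise, undercount and rounding."""
    rows = []
    for year in census_years:
        truth = np.asarray(true_pops[year], dtype=float)
        factor = spec.undercount.get(year, 1.0)
        counts = _noisy_counts(truth * factor, spec.phi_true, spec.noise, rng)
        if spec.random_round:
            counts = random_round_base5(counts, rng)
        for age_lo in CENSUS_AGE_LOS:
            idx = age_lo // 5
            value = int(counts[idx]) if idx < N_AGES else 0
            rows.append((spec.language, year, age_lo, value))
    frame = pd.DataFrame(
        rows, columns=["language", "census_year", "age_lo", "count"]
    )
    return CensusCountTable(frame, rounded_base5=spec.random_round)


def simulate_bundle(
    specs: Sequence[ScenarioSpec],
    schedule: MortalitySchedule,
    fertility: FertilityScheduleTable,
    rng: np.random.Generator,
) -> CensusCountTable:
    """Simulate one census table covering several synthetic languages."""
    frames = []
    rounded = all(s.random_round for s in specs)
    for spec in specs:
        truth = make_true_population(spec, schedule, fertility)
        frames.append(simulate_censuses(truth, spec, rng).frame)
    return CensusCountTable(pd.concat(frames, ignore_index=True), rounded_base5=rounded)


# -- preset scenarios -------------------------------------------------------

def _pyramid(total: float, slope: float, max_age_lo: int = 75) -> np.ndarray:
    """Smooth age pyramid over ages 0 … ``max_age_lo``; exp(slope·age) shape.

    Negative slope → young population, positive → old.
    """
    ages = np.asarray(PROJECTION_AGE_LOS, dtype=float)
    w = np.exp(slope * ages)
    w[ages > max_age_lo] = 0.0
    return total * w / w.sum()


def scenario_presets() -> dict[str, ScenarioSpec]:
    """Named ground-truth scenarios spanning the qualitative regimes.

    Sizes, age structures and transmission levels echo the range seen in
    Canadian census counts of Indigenous first languages: a large growing
    language with high transmission, a large declining one, a small language
    whose transmission has collapsed, and a tiny near-dormant one.
    """
    return {
        "large_growing": ScenarioSpec(
            language="large_growing",
            initial_1981=_pyramid(2500, -0.035),
            xtfr_1981_2001=(1.5, 1.6, 1.7, 1.8, 1.9),
        ),
        "large_declining": ScenarioSpec(
            language="large_declining",
            initial_1981=_pyramid(45000, -0.012),
            xtfr_1981_2001=(1.30, 1.17, 1.053, 0.948, 0.853),
        ),
        "small_declining": ScenarioSpec(
            language="small_declining",
            initial_1981=_pyramid(600, 0.02),
            xtfr_1981_2001=(0.40, 0.25, 0.15, 0.08, 0.01),
        ),
        "tiny_near_dormant": ScenarioSpec(
            language="tiny_near_dormant",
            initial_1981=_pyramid(120, 0.035),
            xtfr_1981_2001=(0.30, 0.20, 0.12, 0.07, 0.04),
        ),
    }


def preset_bundle(n_languages: int = 27, seed: int = 12345) -> list[ScenarioSpec]:
    """A bundle of synthetic languages with varied sizes and trends.

    The first four entries are the named presets; the remainder are drawn
    deterministically from the given seed with log-uniform sizes (60 …
    60 000 speakers in 1981) and transmission trajectories spanning steep
    decline to moderate growth.
    """
    specs = list(scenario_presets().values())
    rng = np.random.Generator(np.random.PCG64(seed))
    for i in range(len(specs), n_languages):
        total = float(np.exp(rng.uniform(np.log(60), np.log(60000))))
        x0 = float(rng.uniform(0.15, 1.8))
        ratio = float(rng.uniform(0.8, 1.1))
        xtfr = tuple(x0 * ratio**k for k in range(5))
        slope = -0.03 if ratio > 1 else float(rng.uniform(-0.02, 0.03))
        specs.append(
            ScenarioSpec(
                language=f"synthetic_{i:02d}",
                initial_1981=_pyramid(total, slope),
                xtfr_1981_2001=xtfr,
            )
        )
    return specs[:n_languages]


# -- synthetic WPP-like schedules ------------------------------------------

LIFETABLE_PERIODS = tuple(range(1981, 2097, 5))


def default_e0_targets() -> dict[tuple[str, int], float]:
    """Labelled life expectancies for the shipped synthetic life table.

    ``default`` rises from 69 years in 1981 to 86.7 in 2096;
    ``synthetic_alt`` runs about 1.5 years lower early on and converges.
    """
    targets = {}
    for period in LIFETABLE_PERIODS:
        frac = (period - 1981) / (2096 - 1981)
        targets[("default", period)] = 69.0 + frac * (86.7 - 69.0)
        targets[("synthetic_alt", period)] = 67.5 + frac * (86.0 - 67.5)
    return targets


def _hazard(ages: np.ndarray) -> np.ndarray:
    """Reference Siler-style hazard: infant + background + senescent terms."""
    return 0.02 * np.exp(-0.6 * ages) + 2e-4 + 2.8e-5 * np.exp(0.095 * ages)


def _e0_single_year(k: float) -> float:
    """Life expectancy under hazard k·h on a one-year grid, closed at 100."""
    ages = np.arange(0, 101, 1.0)
    cumh = integrate.cumulative_trapezoid(k * _hazard(ages), ages, initial=0.0)
    surv = np.exp(-cumh)
    surv[-1] = 0.0  # maximum age at death
    return float(np.trapezoid(surv, ages))


def _q5_ladder(k: float) -> np.ndarray:
    """Five-year probabilities of dying under hazard k·h (q(95–99) = 1)."""
    ages = np.arange(0, 101, 1.0)
    cumh = integrate.cumulative_trapezoid(k * _hazard(ages), ages, initial=0.0)
    surv = np.exp(-cumh)
    q5 = np.zeros(N_AGES)
    for i, lo in enumerate(PROJECTION_AGE_LOS):
        q5[i] = 1.0 - surv[lo + 5] / surv[lo]
    q5[-1] = 1.0
    return q5


def make_synthetic_lifetable(
    e0_targets: Mapping[tuple[str, int], float] | None = None,
) -> MortalitySchedule:
    """Build a life table hitting labelled e0 values by scaling the hazard.

    The scale factor is solved per (group, period) against a one-year-grid
    life expectancy, so the shipped q5 ladder is an honest abridgement that
    the five-year closure should reproduce to a few tenths of a year.
    """
    if e0_targets is None:
        e0_targets = default_e0_targets()
    rows = []
    for (group, period), e0 in sorted(e0_targets.items()):
        k = optimize.brentq(lambda k: _e0_single_year(k) - e0, 1e-3, 20.0)
        for age_lo, q in zip(PROJECTION_AGE_LOS, _q5_ladder(k)):
            rows.append((group, period, age_lo, q))
    frame = pd.DataFrame(rows, columns=["pop_group", "period_start", "age_lo", "q5"])
    return MortalitySchedule(frame)


def make_synthetic_fertility() -> FertilityScheduleTable:
    """WPP-like pooled fertility profiles: TFR ≈ 3.4 in 2001, ≈ 1.8 in 2100.

    The 2001 profile peaks at ages 20–29 (high-fertility regime); the 2100
    profile is lower and shifted toward ages 25–34, emulating postponement.
    """
    rows = []
    asfr_2001 = [0.100, 0.170, 0.170, 0.120, 0.070, 0.030, 0.010]
    asfr_2100 = [0.020, 0.070, 0.100, 0.090, 0.050, 0.018, 0.004]
    for year, rates in ((2001, asfr_2001), (2100, asfr_2100)):
        for age_lo, rate in zip(range(15, 50, 5), rates):
            rows.append(("default", year, age_lo, rate))
    return FertilityScheduleTable(
        pd.DataFrame(rows, columns=["region", "year", "age_lo", "asfr"])
    )
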