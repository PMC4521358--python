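"""Synthetic ground truths and survey-style calibration targets.

Every stage of the pipeline is testable without external data: a
:class:`TruthScenario` holds a known parameter set and a starting
population; ``generate_targets`` forward-simulates it in expected-value
mode, reads off the survey-style outcomes (three waves for fertility,
education and migration lookback; annual mortality, population-size
and life-expectancy series) and perturbs the calibration rows with
Normal noise matched to their stated 95% intervals.

The default world is a scaled stylization of a low/middle-income
demographic transition: declining fertility quantum, mortality falling
over calendar time and declining with education, rising educational
attainment, and rural-to-urban migration that increases with
education.  The starting population is 1e5 women (proportions and
rates are scale-free; absolute population targets are generated on the
synthetic scale).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fertility import FertilityParams
from .mortality import EducationRR, LeeCarterParams
from .params import ParameterSet, VariantSpec
from .simulator import OutcomePlan, SimulationConfig, simulate
from .state import (
    DEFAULT_AGE_CAP,
    MIG_NEVER,
    N_EDUCATION,
    N_MIG,
    N_RESIDENCE,
    PopulationState,
    Residence,
)
from .targets import TargetSet
from .transitions import EducationTrendParams, MigrationParams, newborn_education_distribution

logger = logging.getLogger(__name__)

SCENARIOS = ("full_effects", "no_education_effects", "no_migration", "static")

FERTILITY_AGE_BANDS = ((15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44), (45, 49))
MORTALITY_AGE_BANDS = (
    (0, 0),
    (1, 4),
    (5, 14),
    (15, 24),
    (25, 34),
    (35, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 84),
)
MIGRATION_AGE_BAND = (15, 49)
EDUCATION_AGE_BAND = (20, 24)


@dataclass
class NoiseModel:
    """Relative 95% CI half-widths per target class (0 = exact)."""

    proportions: float = 0.05  # fertility, mortality, education, migration rows
    population: float = 0.02
    # absolute CI half-width floors so near-zero rates keep usable intervals
    abs_floor: float = 1e-4


@dataclass
class TruthScenario:
    name: str
    params: ParameterSet
    initial_state: PopulationState
    sim_config: SimulationConfig
    noise: NoiseModel
    wave_offsets: tuple[int, ...] = (1, 7, 14)
    mortality_series_years: int = 17
    seed: int = 0

    @property
    def wave_years(self) -> tuple[int, ...]:
        return tuple(self.sim_config.start_year + o for o in self.wave_offsets)


def _truth_parameters(start_year: int) -> ParameterSet:
    """The full-effects ground truth (model variant v3)."""
    # fertility quantum declines with education and is lower in towns
    F = np.array([[3.6, 3.2, 2.6, 1.8], [4.5, 4.0, 3.2, 2.2]])  # (urban, rural) x E0..E3
    a = np.array([[23.0, 23.5, 24.5, 26.5], [22.0, 22.5, 23.5, 25.5]])
    b = np.array([[10.0, 10.0, 10.5, 11.0], [10.5, 10.5, 11.0, 11.5]])
    trend_F = np.array([[-0.030, -0.028, -0.022, -0.012], [-0.035, -0.032, -0.026, -0.015]])
    fert = FertilityParams(F=F, a=a, b=b, trend_F=trend_F, reference_year=start_year)
    # mortality surface: infant / child / adult clusters per residence
    lc = LeeCarterParams(
        c=np.array([[-3.3, -6.3, -3.8], [-2.9, -5.9, -3.6]]),
        beta_year=np.array([[-0.030, -0.028, -0.020], [-0.030, -0.028, -0.020]]),
        beta_age=np.array([[0.0, -0.12, 0.088], [0.0, -0.12, 0.088]]),
        reference_year=start_year,
        reference_ages=LeeCarterParams.default_reference_ages(),
    )
    # relative risk of death declines monotonically with schooling
    rr = EducationRR(np.array([[0.92, 0.76, 0.55, 0.38], [1.00, 0.89, 0.72, 0.56]]))
    # rural-to-urban moves rise with education and drift upward
    mig = MigrationParams(
        base_rate=np.array([[0.003, 0.005, 0.008, 0.012], [0.0, 0.0, 0.0, 0.0]]),
        trend=np.array([[1.0e-4, 1.5e-4, 2.0e-4, 2.5e-4], [0.0, 0.0, 0.0, 0.0]]),
        reference_year=start_year,
    )
    edu = EducationTrendParams(
        baseline=np.array([[0.25, 0.25, 0.40, 0.10], [0.55, 0.25, 0.17, 0.03]]),
        trend=np.array(
            [[-0.008, 0.001, 0.005, 0.002], [-0.012, 0.004, 0.007, 0.001]]
        ),
        reference_year=start_year,
    )
    return ParameterSet(
        variant="v3",
        fertility=fert,
        lee_carter=lc,
        education_rr=rr,
        migration=mig,
        education_trend=edu,
    )


def make_initial_population(
    params: ParameterSet,
    start_year: int = 1992,
    size: float = 1e5,
    urban_share: float = 0.26,
    age_cap: int = DEFAULT_AGE_CAP,
) -> PopulationState:
    """Deterministic starting population.

    A smooth quasi-stable age pyramid (exponentially tapering with
    age), the given urban share at every age, education assigned per
    cohort from the birth-year education distribution (so attainment
    already trends across living cohorts at the start), and no recorded
    migration history.
    """
    ages = np.arange(age_cap + 1)
    pyramid = np.exp(-0.028 * ages) * np.exp(-np.maximum(ages - 70, 0) ** 2 / (2 * 15.0**2))
    pyramid /= pyramid.sum()
    counts = np.zeros((age_cap + 1, N_RESIDENCE, N_EDUCATION, N_MIG))
    for res, share in ((Residence.URBAN, urban_share), (Residence.RURAL, 1 - urban_share)):
        for age in ages:
            dist = newborn_education_distribution(
                params.education_trend, start_year - int(age), int(res)
            )
            counts[age, res, :, MIG_NEVER] = size * share * pyramid[age] * dist
    return PopulationState(year=start_year, counts=counts, age_cap=age_cap)


def make_truth(
    name: str,
    seed: int = 0,
    start_year: int = 1992,
    end_year: int = 2025,
    size: float = 1e5,
    noise: NoiseModel | None = None,
) -> TruthScenario:
    """Build a named ground-truth scenario.

    ``full_effects`` carries every process; ``no_education_effects``
    removes all education differentials (unit RRs, education-invariant
    fertility, frozen attainment); ``no_migration`` zeroes moves;
    ``static`` zeroes every secular trend.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    params = _truth_parameters(start_year)
    if name == "no_education_effects":
        params.education_rr.rr[:] = 1.0
        params.education_trend.trend[:] = 0.0
        for fld in ("F", "a", "b", "trend_F"):
            arr = getattr(params.fertility, fld)
            arr[:, :] = arr[:, :1]
    elif name == "no_migration":
        params.migration.base_rate[:] = 0.0
        params.migration.trend[:] = 0.0
    elif name == "static":
        params.fertility.trend_F[:] = 0.0
        params.lee_carter.beta_year[:] = 0.0
        params.migration.trend[:] = 0.0
        params.education_trend.trend[:] = 0.0
    initial = make_initial_population(params, start_year, size)
    cfg = SimulationConfig(
        start_year=start_year, end_year=end_year, mode="expected_value", seed=seed
    )
    return TruthScenario(
        name=name,
        params=params,
        initial_state=initial,
        sim_config=cfg,
        noise=noise if noise is not None else NoiseModel(),
        seed=seed,
    )


def _target_grid(scenario: TruthScenario) -> pd.DataFrame:
    """Empty target rows (no estimates yet) on the survey-style grid."""
    rows = []
    y0 = scenario.sim_config.start_year
    waves = scenario.wave_years
    res_names = ("urban", "rural")
    edu_names = ("E0", "E1", "E2", "E3")
    for wave in waves:
        for res in res_names:
            for edu in edu_names:
                for lo, hi in FERTILITY_AGE_BANDS:
                    rows.append(
                        dict(cls="fertility", year=wave, age_low=lo, age_high=hi, residence=res, education=edu)
                    )
    for year in range(y0, y0 + scenario.mortality_series_years):
        for res in res_names:
            for lo, hi in MORTALITY_AGE_BANDS:
                rows.append(dict(cls="mortality", year=year, age_low=lo, age_high=hi, residence=res))
    for wave in waves:
        for res in res_names:
            for edu in edu_names:
                rows.append(
                    dict(
                        cls="education",
                        year=wave,
                        age_low=EDUCATION_AGE_BAND[0],
                        age_high=EDUCATION_AGE_BAND[1],
                        residence=res,
                        education=edu,
                    )
                )
    for wave in waves:
        for res in res_names:
            for edu in edu_names:
                for window in ("6y", "12y", "ever"):
                    rows.append(
                        dict(
                            cls="migration",
                            year=wave,
                            age_low=MIGRATION_AGE_BAND[0],
                            age_high=MIGRATION_AGE_BAND[1],
                            residence=res,
                            education=edu,
                            window=window,
                        )
                    )
    for year in range(y0, y0 + scenario.mortality_series_years):
        for res in res_names:
            rows.append(dict(cls="population_size", year=year, residence=res))
    for year in range(y0, y0 + scenario.mortality_series_years):
        rows.append(dict(cls="life_expectancy_validation", year=year))
    df = pd.DataFrame(rows).rename(columns={"cls": "class"})
    for col in ("age_low", "age_high"):
        if col not in df:
            df[col] = np.nan
    for col, default in (("residence", "all"), ("education", "all"), ("window", "")):
        df[col] = df.get(col, default)
        df[col] = df[col].fillna(default)
    return df


def generate_targets(
    scenario: TruthScenario,
    noise_scale: float = 1.0,
    perturb_validation: bool = False,
) -> tuple[TargetSet, PopulationState]:
    """Noisy survey-style targets from a known truth.

    The truth is forward-simulated in expected-value mode; target
    estimates are the extracted outcomes perturbed with Normal noise of
    standard deviation (CI half-width)/1.96, so the written 95%
    intervals are calibrated.  Negative perturbed rates are truncated
    at zero with a warning.  ``noise_scale=0`` yields exact targets.
    """
    traj = simulate(scenario.params, scenario.initial_state, scenario.sim_config)
    grid = _target_grid(scenario)
    grid["calibration"] = grid["class"] != "life_expectancy_validation"
    plan = OutcomePlan(grid, scenario.sim_config.age_cap)
    truth_vals = plan.evaluate(traj, scenario.params).values

    nm = scenario.noise
    rel = np.where(
        grid["class"].to_numpy() == "population_size", nm.population, nm.proportions
    )
    half = np.maximum(rel * np.abs(truth_vals), nm.abs_floor)
    # life-expectancy rows get a CI on the same relative width
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed) & 0x7FFFFFFF, 202]))
    sd = noise_scale * half / 1.96
    perturb = rng.standard_normal(len(grid)) * sd
    is_validation = ~grid["calibration"].to_numpy(bool)
    if not perturb_validation:
        perturb[is_validation] = 0.0
    est = truth_vals + perturb
    neg = est < 0
    if np.any(neg):
        warnings.warn(f"{int(neg.sum())} perturbed targets truncated at zero", stacklevel=2)
        est = np.maximum(est, 0.0)
    grid["estimate"] = est
    # perturbed education prevalences are renormalized per survey group,
    # as published prevalence tables sum to one
    is_edu = (grid["class"] == "education").to_numpy()
    if np.any(is_edu):
        sub = grid.loc[is_edu]
        sums = sub.groupby(["year", "residence"])["estimate"].transform("sum")
        grid.loc[is_edu, "estimate"] = np.where(sums > 0, sub["estimate"] / sums, 0.25)
    # lookback windows are nested by construction (6y within 12y within
    # ever); independent noise can invert them, so restore the order
    is_mig = (grid["class"] == "migration").to_numpy()
    if np.any(is_mig):
        order = {"6y": 0, "12y": 1, "ever": 2}
        sub = grid.loc[is_mig]
        for _, g in sub.groupby(["year", "residence", "education", "age_low"]):
            g = g.sort_values("window", key=lambda s: s.map(order))
            grid.loc[g.index, "estimate"] = np.sort(g["estimate"].to_numpy(float))
    est = grid["estimate"].to_numpy(float)
    grid["ci_low"] = np.minimum(est - half, est)
    grid["ci_high"] = est + half
    return TargetSet(grid), scenario.initial_state.copy()


def recovery_report(chains, scenario: TruthScenario) -> pd.DataFrame:
    """Per-parameter recovery table against the scenario's truth.

    Columns: truth, posterior median, central 95% credible interval,
    coverage flag, relative error of the median.
    """
    spec = VariantSpec(scenario.params.variant)
    truth = spec.to_vector(scenario.params)
    names = spec.names
    draws = np.concatenate([c.draws for c in chains], axis=0)
    chain_names = chains[0].names
    if list(chain_names) != list(names):
        raise ValueError("chain parameter names do not match the scenario's variant")
    med = np.median(draws, axis=0)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    covered = (lo <= truth) & (truth <= hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(truth != 0, np.abs(med - truth) / np.abs(truth), np.abs(med - truth))
    df = pd.DataFrame(
        {
            "parameter": names,
            "truth": truth,
            "posterior_median": med,
            "ci_low": lo,
            "ci_high": hi,
            "covered": covered,
            "relative_error": rel_err,
        }
    )
    df.attrs["coverage"] = float(covered.mean())
    return df


def write_scenario(scenario: TruthScenario, out_dir, noise_scale: float = 1.0) -> Path:
    """Write manifest + per-class CSVs + initial population + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    targets, initial = generate_targets(scenario, noise_scale=noise_scale)
    manifest = targets.write_manifest(out_dir)
    initial.to_csv(out_dir / "initial_population.csv")
    scenario.params.to_json(out_dir / "truth.json")
    return manifest
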