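"""Annual population projection under competing risks.

Each simulated year, every stratum is exposed to a mortality hazard and
(for the most complex variant) a migration hazard.  The two risks are
resolved jointly with the standard competing-risks identities

    H = sum of hazards
    P(event i) = (h_i / H) * (1 - exp(-H)),   P(no event) = exp(-H)

after which survivors age by one year, migration lookback counters
advance, and births — computed from start-of-year exposures via the
cumulative fertility curve — enter at age 0 with their mother's
residence and a birth-cohort education category.

Two execution modes share the same state: expected-value (deterministic
fractional flows — smooth, used inside calibration) and stochastic
(integer multinomial/Poisson draws per stratum, reproducible from the
seed; one generator per (seed, year) so that scenario arms share common
random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mortality import hazard_schedule
from .params import ParameterSet
from .state import (
    DEFAULT_AGE_CAP,
    MIG_NEVER,
    MIG_WINDOWS,
    N_EDUCATION,
    N_MIG,
    N_RESIDENCE,
    PopulationState,
    Residence,
    build_life_table,
)
from .targets import TargetSet
from .transitions import DIR_R2U, DIR_U2R


@dataclass
class SimulationConfig:
    start_year: int = 1992
    end_year: int = 2025
    mode: str = "expected_value"  # or "stochastic"
    seed: int = 0
    fraction_female: float = 0.487
    model_variant: str = "v3"
    age_cap: int = DEFAULT_AGE_CAP

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")
        if self.mode not in ("expected_value", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.fraction_female < 1.0:
            raise ValueError("fraction_female must lie in (0, 1)")


def competing_risk_probabilities(hazards) -> np.ndarray:
    """Annual event probabilities from per-year hazards.

    Returns an array of length ``len(hazards) + 1``: one probability
    per event type followed by the no-event (survival) probability;
    sums to 1 exactly.
    """
    h = np.asarray(hazards, dtype=float)
    if np.any(h < 0):
        raise ValueError("hazards must be non-negative")
    H = h.sum()
    if H == 0:
        return np.concatenate([np.zeros_like(h), [1.0]])
    surv = np.exp(-H)
    probs = (h / H) * (1.0 - surv)
    return np.concatenate([probs, [1.0 - probs.sum()]])


@dataclass
class Trajectory:
    """Annual states plus per-year event tallies."""

    years: np.ndarray  # (T,)
    counts: np.ndarray  # (T, A, 2, 4, M)
    births: np.ndarray  # (T-1,) events during year t
    deaths: np.ndarray
    moves: np.ndarray
    config: SimulationConfig
    hazards: np.ndarray | None = None  # (T, A, 2, 4) mortality, cached for outcome extraction

    @property
    def age_cap(self) -> int:
        return self.counts.shape[1] - 1

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise ValueError(f"year {year} outside simulated horizon {self.years[0]}-{self.years[-1]}")
        return idx

    def state(self, year: int) -> PopulationState:
        return PopulationState(year, self.counts[self.year_index(year)].copy(), self.age_cap)

    def totals(self) -> np.ndarray:
        """(T, 2) population by residence."""
        return self.counts.sum(axis=(1, 3, 4))


def _newborn_distributions(params: ParameterSet, year: int) -> np.ndarray:
    """(2, 4) education distribution of girls born in ``year``."""
    et = params.education_trend
    raw = np.maximum(et.baseline + et.trend * (year - et.reference_year), 0.0)
    totals = raw.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(f"education trend extrapolation to {year} leaves no probability mass")
    dist = raw / totals[:, None]
    iv = params.education_intervention_year
    if iv is not None and year >= iv:
        # universal primary education for rural birth cohorts: the
        # no-schooling mass moves into the 1-5-years category
        dist[Residence.RURAL, 1] += dist[Residence.RURAL, 0]
        dist[Residence.RURAL, 0] = 0.0
    return dist


class _YearSchedules:
    """Per-year hazard, fertility and event-probability grids.

    Everything that depends on (parameters, calendar year) but not on
    the evolving state is computed once, vectorized over the horizon.
    Arrays are indexed ``[t, age, residence, education]`` with
    ``t = year - start_year``.
    """

    def __init__(self, params: ParameterSet, config: SimulationConfig):
        T = config.end_year - config.start_year + 1
        A = config.age_cap + 1
        years = np.arange(config.start_year, config.end_year + 1)
        ages = np.arange(A, dtype=float)

        lc = params.lee_carter
        cl = np.where(ages < 1, 0, np.where(ages <= 10, 1, 2))
        dy = (years - lc.reference_year)[:, None]  # (T,1)
        mu = np.empty((T, A, N_RESIDENCE, N_EDUCATION))
        for res in range(N_RESIDENCE):
            log_base = (
                lc.c[res, cl][None, :]
                + lc.beta_year[res, cl][None, :] * dy
                + (lc.beta_age[res, cl] * (ages - lc.reference_ages[cl]))[None, :]
            )  # (T, A)
            mu[:, :, res, :] = np.exp(log_base)[:, :, None] * params.education_rr.rr[res]
        self.mu = mu

        fert = params.fertility
        from .fertility import R_GOMPERTZ

        shape = 0.5 ** (
            R_GOMPERTZ ** ((np.arange(A + 1, dtype=float)[:, None, None] - fert.a) / fert.b)
        )  # (A+1, 2, 4), the G curve at unit quantum
        increments = shape[1:] - shape[:-1]  # (A, 2, 4)
        F_eff = np.maximum(0.0, fert.F + fert.trend_F * (years[:, None, None] - fert.reference_year))
        self.frate = F_eff[:, None] * increments[None]  # (T, A, 2, 4)

        mig = np.clip(
            params.migration.base_rate
            + params.migration.trend * (years[:, None, None] - params.migration.reference_year),
            0.0,
            1.0,
        )  # (T, 2 dir, 4)
        m = np.empty((T, N_RESIDENCE, N_EDUCATION))
        m[:, Residence.RURAL] = mig[:, DIR_R2U]
        m[:, Residence.URBAN] = mig[:, DIR_U2R]
        m_full = np.broadcast_to(m[:, None], (T, A, N_RESIDENCE, N_EDUCATION))

        H = mu + m_full
        Hsafe = np.where(H > 0, H, 1.0)
        frac = np.where(H > 0, -np.expm1(-H) / Hsafe, 1.0)
        self.p_death = mu * frac
        self.p_move = m_full * frac
        self.p_stay = np.exp(-H)

        self.newborn_dist = np.stack(
            [_newborn_distributions(params, int(y)) for y in years]
        )  # (T, 2, 4)


def _step_arrays(
    counts: np.ndarray,
    t: int,
    sched: _YearSchedules,
    config: SimulationConfig,
    rng: np.random.Generator | None,
    out: np.ndarray,
) -> dict:
    """One annual step on raw count arrays; writes the next year into ``out``."""
    A = config.age_cap + 1
    p_death = sched.p_death[t]
    p_move = sched.p_move[t]
    p_stay = sched.p_stay[t]

    exposure = counts.sum(axis=-1)  # start-of-year women (A,2,4)
    if config.mode == "expected_value":
        stay = counts * p_stay[..., None]
        movers_total = exposure * p_move  # (A,2,4); within-cell hazards are uniform
        deaths_sum = float((exposure * p_death).sum())
    else:
        if rng is None:
            raise ValueError("stochastic mode requires a random generator")
        n = np.rint(counts).astype(np.int64)
        if not np.array_equal(n, counts):
            raise ValueError("stochastic mode requires integer counts")
        pvals = np.broadcast_to(
            np.stack([p_death, p_move, p_stay], axis=-1)[..., None, :],
            (A, N_RESIDENCE, N_EDUCATION, N_MIG, 3),
        )
        draws = rng.multinomial(n, pvals)
        movers_total = draws[..., 1].sum(axis=-1).astype(float)
        stay = draws[..., 2].astype(float)
        deaths_sum = float(draws[..., 0].sum())

    # survivors: advance the migration counter and age by one year in a
    # single shifted write; the terminal age is absorbing
    out.fill(0.0)
    out[1:, :, :, MIG_NEVER] = stay[:-1, :, :, MIG_NEVER]
    out[1:, :, :, 2:] = stay[:-1, :, :, 1:-1]
    out[1:, :, :, -1] += stay[:-1, :, :, -1]
    out[-1, :, :, MIG_NEVER] += stay[-1, :, :, MIG_NEVER]
    out[-1, :, :, 2:] += stay[-1, :, :, 1:-1]
    out[-1, :, :, -1] += stay[-1, :, :, -1]
    # movers arrive in the other residence with a reset counter, aged
    out[1:, Residence.URBAN, :, 1] += movers_total[:-1, Residence.RURAL, :]
    out[1:, Residence.RURAL, :, 1] += movers_total[:-1, Residence.URBAN, :]
    out[-1, Residence.URBAN, :, 1] += movers_total[-1, Residence.RURAL, :]
    out[-1, Residence.RURAL, :, 1] += movers_total[-1, Residence.URBAN, :]

    births_by_res = (exposure * sched.frate[t]).sum(axis=(0, 2)) * config.fraction_female  # (2,)
    dist = sched.newborn_dist[t]  # (2,4)
    if config.mode == "expected_value":
        newborns = births_by_res[:, None] * dist
    else:
        newborns = np.zeros((N_RESIDENCE, N_EDUCATION))
        for res in range(N_RESIDENCE):
            total = rng.poisson(births_by_res[res])
            if total > 0:
                newborns[res] = rng.multinomial(total, dist[res])
    out[0, :, :, MIG_NEVER] += newborns

    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite counts after annual step (parameter pathology)")
    tallies = {
        "births": float(newborns.sum()),
        "deaths": deaths_sum,
        "moves": float(movers_total.sum()),
    }
    return tallies


def step_year(
    state: PopulationState,
    params: ParameterSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationState, dict]:
    """Advance the population one calendar year.

    Deaths and moves are resolved jointly by competing risks, survivors
    age, migration counters advance, and births (from start-of-year
    exposures, so women dying within the year still contribute) enter
    at age 0.  Returns the new state and the year's event tallies.
    """
    one_year = SimulationConfig(
        **{**config.__dict__, "start_year": state.year, "end_year": state.year + 1}
    )
    sched = _YearSchedules(params, one_year)
    out = np.empty_like(state.counts)
    tallies = _step_arrays(state.counts, 0, sched, config, rng, out)
    return PopulationState(state.year + 1, out, config.age_cap), tallies


def simulate(
    params: ParameterSet,
    initial_state: PopulationState,
    config: SimulationConfig,
) -> Trajectory:
    """Iterate annual steps from start_year to end_year inclusive.

    Deterministic given (params, initial state, seed, mode); in
    stochastic mode one generator is derived per (seed, year), so two
    runs sharing a seed use common random numbers year by year.
    """
    if initial_state.year != config.start_year:
        raise ValueError(
            f"initial state year {initial_state.year} != config start year {config.start_year}"
        )
    if initial_state.age_cap != config.age_cap:
        raise ValueError("initial state and config disagree on age_cap")
    T = config.end_year - config.start_year + 1
    A = config.age_cap + 1
    counts = np.empty((T, A, N_RESIDENCE, N_EDUCATION, N_MIG))
    counts[0] = initial_state.counts
    sched = _YearSchedules(params, config)
    births = np.zeros(max(T - 1, 0))
    deaths = np.zeros(max(T - 1, 0))
    moves = np.zeros(max(T - 1, 0))
    for t in range(T - 1):
        year = config.start_year + t
        rng = None
        if config.mode == "stochastic":
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), int(year) & 0x7FFFFFFF])
            )
        tallies = _step_arrays(counts[t], t, sched, config, rng, counts[t + 1])
        births[t] = tallies["births"]
        deaths[t] = tallies["deaths"]
        moves[t] = tallies["moves"]
    years = np.arange(config.start_year, config.end_year + 1)
    return Trajectory(
        years=years,
        counts=counts,
        births=births,
        deaths=deaths,
        moves=moves,
        config=config,
        hazards=sched.mu,
    )


# ---------------------------------------------------------------------------
# Outcome extraction


@dataclass
class ModelOutcomes:
    """Model predictions aligned one-to-one with a TargetSet's rows."""

    values: np.ndarray
    target_set: TargetSet

    def by_class(self, cls: str) -> np.ndarray:
        return self.values[(self.target_set.df["class"] == cls).to_numpy()]


_RES_INDEX = {"urban": 0, "rural": 1}
_EDU_INDEX = {"E0": 0, "E1": 1, "E2": 2, "E3": 3}


class OutcomePlan:
    """Precompiled index arrays mapping target rows to model summaries.

    Building the plan once per TargetSet keeps per-evaluation cost low
    inside MCMC loops.
    """

    def __init__(self, target_set, age_cap: int = DEFAULT_AGE_CAP):
        self.target_set = target_set
        self.age_cap = age_cap
        df = target_set.df if isinstance(target_set, TargetSet) else target_set
        self.n = len(df)
        cls = df["class"].to_numpy()
        self.rows: dict[str, np.ndarray] = {c: np.flatnonzero(cls == c) for c in np.unique(cls)}
        self.year = df["year"].to_numpy(float).astype(int)
        self.res = np.array([_RES_INDEX.get(r, -1) for r in df["residence"].astype(str)])
        self.edu = np.array([_EDU_INDEX.get(e, -1) for e in df["education"].astype(str)])
        age_low = df["age_low"].to_numpy(float)
        age_high = df["age_high"].to_numpy(float)
        self.age_low = np.where(np.isnan(age_low), 0, age_low).astype(int)
        self.age_high = np.where(np.isnan(age_high), age_cap, age_high).astype(int)
        self.window = df["window"].astype(str).to_numpy()

    def evaluate(self, traj: Trajectory, params: ParameterSet) -> ModelOutcomes:
        if self.n and (
            self.year.min() < int(traj.years[0]) or self.year.max() > int(traj.years[-1])
        ):
            raise ValueError(
                f"targets span years {self.year.min()}-{self.year.max()} outside the "
                f"simulated horizon {traj.years[0]}-{traj.years[-1]}"
            )
        values = np.full(self.n, np.nan)
        self._population(traj, values)
        self._fertility(params, values)
        self._mortality(traj, params, values)
        self._education(traj, values)
        self._migration(traj, values)
        self._life_expectancy(traj, params, values)
        return ModelOutcomes(values=values, target_set=self.target_set)

    def _population(self, traj, values) -> None:
        rows = self.rows.get("population_size")
        if rows is None:
            return
        totals = traj.totals()  # (T, 2)
        t_idx = self.year[rows] - int(traj.years[0])
        res = self.res[rows]
        vals = np.where(res >= 0, totals[t_idx, np.clip(res, 0, 1)], totals[t_idx].sum(axis=1))
        values[rows] = vals

    def _fertility(self, params, values) -> None:
        """Children ever born ~ cumulative curve at the band's mid-age,
        with the quantum effective in the survey wave's year."""
        rows = self.rows.get("fertility")
        if rows is None:
            return
        res = self.res[rows]
        edu = self.edu[rows]
        mid = (self.age_low[rows] + self.age_high[rows] + 1) / 2.0
        fert = params.fertility
        F_eff = np.maximum(
            0.0,
            fert.F[res, edu] + fert.trend_F[res, edu] * (self.year[rows] - fert.reference_year),
        )
        a = params.fertility.a[res, edu]
        b = params.fertility.b[res, edu]
        from .fertility import R_GOMPERTZ

        g = np.where(F_eff > 0, F_eff * 0.5 ** (R_GOMPERTZ ** ((mid - a) / b)), 0.0)
        values[rows] = g

    def _mortality(self, traj, params, values) -> None:
        """Annual death probability over an age band: 1 - exp(-mu_bar)
        with mu_bar the count-weighted mean hazard across the band and
        education categories."""
        rows = self.rows.get("mortality")
        if rows is None:
            return
        for year in np.unique(self.year[rows]):
            sel = rows[self.year[rows] == year]
            t = traj.year_index(year)
            mu = (
                traj.hazards[t]
                if traj.hazards is not None
                else hazard_schedule(params.lee_carter, params.education_rr, int(year), self.age_cap)
            )
            w = traj.counts[t].sum(axis=-1)  # (A,2,4)
            wmu = (w * mu).sum(axis=2)  # (A,2)
            wsum = w.sum(axis=2)
            mu_unw = mu.mean(axis=2)  # fallback for empty bands
            cum_wmu = np.concatenate([np.zeros((1, 2)), np.cumsum(wmu, axis=0)])
            cum_w = np.concatenate([np.zeros((1, 2)), np.cumsum(wsum, axis=0)])
            cum_unw = np.concatenate([np.zeros((1, 2)), np.cumsum(mu_unw, axis=0)])
            lo = self.age_low[sel]
            hi = np.minimum(self.age_high[sel], self.age_cap)
            r = np.clip(self.res[sel], 0, 1)
            num = cum_wmu[hi + 1, r] - cum_wmu[lo, r]
            den = cum_w[hi + 1, r] - cum_w[lo, r]
            unw = (cum_unw[hi + 1, r] - cum_unw[lo, r]) / (hi + 1 - lo)
            mu_bar = np.where(den > 0, num / np.where(den > 0, den, 1.0), unw)
            values[sel] = -np.expm1(-mu_bar)

    def _education(self, traj, values) -> None:
        """Prevalence of each category among women aged 20-24."""
        rows = self.rows.get("education")
        if rows is None:
            return
        for year in np.unique(self.year[rows]):
            sel = rows[self.year[rows] == year]
            t = traj.year_index(year)
            lo = self.age_low[sel]
            hi = self.age_high[sel]
            for j, row in enumerate(sel):
                block = traj.counts[t, lo[j] : hi[j] + 1, self.res[row]]  # (ages,4,M)
                by_edu = block.sum(axis=(0, 2))
                total = by_edu.sum()
                values[row] = by_edu[self.edu[row]] / total if total > 0 else 0.0

    def _migration(self, traj, values) -> None:
        """Share of a stratum whose last move falls in the lookback window."""
        rows = self.rows.get("migration")
        if rows is None:
            return
        for year in np.unique(self.year[rows]):
            sel = rows[self.year[rows] == year]
            t = traj.year_index(year)
            c = traj.counts[t]  # (A,2,4,M)
            cum_tot = np.concatenate(
                [np.zeros((1,) + c.shape[1:3]), np.cumsum(c.sum(axis=-1), axis=0)]
            )
            cum_win = {
                w: np.concatenate(
                    [np.zeros((1,) + c.shape[1:3]), np.cumsum(c[..., mask].sum(axis=-1), axis=0)]
                )
                for w, mask in MIG_WINDOWS.items()
            }
            lo = self.age_low[sel]
            hi = np.minimum(self.age_high[sel], self.age_cap)
            r = np.clip(self.res[sel], 0, 1)
            e = self.edu[sel]
            den = cum_tot[hi + 1, r, e] - cum_tot[lo, r, e]
            for j, row in enumerate(sel):
                cw = cum_win[self.window[row]]
                num = cw[hi[j] + 1, r[j], e[j]] - cw[lo[j], r[j], e[j]]
                values[row] = num / den[j] if den[j] > 0 else 0.0

    def _life_expectancy(self, traj, params, values) -> None:
        """Period e0 from the year's count-weighted aggregate hazards."""
        rows = self.rows.get("life_expectancy_validation")
        if rows is None:
            return
        for year in np.unique(self.year[rows]):
            sel = rows[self.year[rows] == year]
            t = traj.year_index(year)
            mu = (
                traj.hazards[t]
                if traj.hazards is not None
                else hazard_schedule(params.lee_carter, params.education_rr, int(year), self.age_cap)
            )
            w = traj.counts[t].sum(axis=-1)  # (A,2,4)
            num = (w * mu).sum(axis=(1, 2))
            den = w.sum(axis=(1, 2))
            mu_agg = np.where(den > 0, num / np.where(den > 0, den, 1.0), mu.mean(axis=(1, 2)))
            values[sel] = build_life_table(mu_agg).e0


def extract_outcomes(traj: Trajectory, target_set: TargetSet, params: ParameterSet) -> ModelOutcomes:
    """Model-predicted values for every target row of ``target_set``."""
    plan = OutcomePlan(target_set, traj.age_cap)
    return plan.evaluate(traj, params)
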