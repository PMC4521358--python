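"""Stratified population state, stratum grids, and life-table utilities.

The population of females is stratified along four axes:

* single-year age ``0 .. age_cap`` (default cap 110),
* urban/rural residence,
* educational attainment in four categories (0, 1-5, 6-12, >12 years of
  schooling), fixed at birth,
* migration history, tracked as years since the last urban/rural move so
  that survey-style lookback windows (moved within 6 years, within 12
  years, ever) can be answered exactly.

Counts live in a dense ``numpy`` array of shape
``(age_cap + 1, 2, 4, N_MIG)``; expected-value mode stores real-valued
counts, stochastic mode stores integers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_AGE_CAP = 110

N_RESIDENCE = 2
N_EDUCATION = 4

# Migration axis: index 0 = never moved; index 1 + k = last move was k
# years ago, k = 0..12 with k = 12 absorbing ("12 or more years ago").
MIG_NEVER = 0
MIG_YEARS_MAX = 12
N_MIG = 2 + MIG_YEARS_MAX  # 14


class Residence(enum.IntEnum):
    URBAN = 0
    RURAL = 1


class Education(enum.IntEnum):
    """Years of schooling: 0, 1-5, 6-12, >12."""

    E0 = 0
    E1 = 1
    E2 = 2
    E3 = 3


class MigrationBin(enum.IntEnum):
    NEVER = 0
    MOVED_0_5 = 1
    MOVED_6_11 = 2
    MOVED_12_PLUS = 3


class MoveDirection(enum.IntEnum):
    NONE = 0
    RURAL_TO_URBAN = 1
    URBAN_TO_RURAL = 2


def migration_bin_of_index(idx: int) -> MigrationBin:
    """Map an internal migration-axis index to its lookback bin."""
    if idx == MIG_NEVER:
        return MigrationBin.NEVER
    years = idx - 1
    if years <= 5:
        return MigrationBin.MOVED_0_5
    if years <= 11:
        return MigrationBin.MOVED_6_11
    return MigrationBin.MOVED_12_PLUS


def direction_of_state(residence: int, mig_idx: int) -> MoveDirection:
    """Direction of the last move, implied by current residence.

    Moves toggle residence, so a mover currently urban last moved
    rural-to-urban and vice versa; never-movers carry no direction.
    """
    if mig_idx == MIG_NEVER:
        return MoveDirection.NONE
    if residence == Residence.URBAN:
        return MoveDirection.RURAL_TO_URBAN
    return MoveDirection.URBAN_TO_RURAL


# Boolean masks over the migration axis for the three lookback windows.
MIG_WINDOW_6Y = np.zeros(N_MIG, dtype=bool)
MIG_WINDOW_6Y[1 : 1 + 6] = True  # moved 0-5 years ago
MIG_WINDOW_12Y = np.zeros(N_MIG, dtype=bool)
MIG_WINDOW_12Y[1 : 1 + 12] = True  # moved 0-11 years ago
MIG_WINDOW_EVER = np.zeros(N_MIG, dtype=bool)
MIG_WINDOW_EVER[1:] = True

MIG_WINDOWS = {"6y": MIG_WINDOW_6Y, "12y": MIG_WINDOW_12Y, "ever": MIG_WINDOW_EVER}


@dataclass
class PopulationState:
    """Counts of women per stratum for one calendar year.

    ``counts[age, residence, education, migration]`` is a person count;
    non-negative reals in expected-value mode, integers in stochastic
    mode.
    """

    year: int
    counts: np.ndarray
    age_cap: int = DEFAULT_AGE_CAP

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (self.age_cap + 1, N_RESIDENCE, N_EDUCATION, N_MIG)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts in population state")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("non-finite counts in population state")

    @classmethod
    def empty(cls, year: int, age_cap: int = DEFAULT_AGE_CAP) -> "PopulationState":
        return cls(
            year=year,
            counts=np.zeros((age_cap + 1, N_RESIDENCE, N_EDUCATION, N_MIG)),
            age_cap=age_cap,
        )

    def copy(self) -> "PopulationState":
        return PopulationState(self.year, self.counts.copy(), self.age_cap)

    def total(self, residence: Residence | None = None) -> float:
        return total_population(self, residence)

    # -- serialization ----------------------------------------------------

    def to_frame(self, drop_empty: bool = True) -> pd.DataFrame:
        """Long-format table: one row per occupied stratum."""
        idx = np.argwhere(self.counts > 0 if drop_empty else np.ones_like(self.counts, bool))
        rows = []
        for age, res, edu, mig in idx:
            rows.append(
                {
                    "year": self.year,
                    "age": int(age),
                    "residence": Residence(res).name.lower(),
                    "education": Education(edu).name,
                    "migration_bin": migration_bin_of_index(mig).name.lower(),
                    "direction": direction_of_state(res, mig).name.lower(),
                    "years_since_move": "" if mig == MIG_NEVER else int(mig - 1),
                    "count": self.counts[age, res, edu, mig],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "year",
                "age",
                "residence",
                "education",
                "migration_bin",
                "direction",
                "years_since_move",
                "count",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, age_cap: int = DEFAULT_AGE_CAP) -> "PopulationState":
        if len(df) == 0:
            raise ValueError("empty population table")
        years = df["year"].unique()
        if len(years) != 1:
            raise ValueError(f"population table spans multiple years: {years}")
        state = cls.empty(int(years[0]), age_cap)
        res_idx = df["residence"].str.upper().map(lambda s: Residence[s].value)
        edu_idx = df["education"].str.upper().map(lambda s: Education[s].value)
        ysm = df.get("years_since_move")
        bins = df["migration_bin"].str.upper()
        mig_idx = np.zeros(len(df), dtype=int)
        for i, (b, y) in enumerate(zip(bins, ysm if ysm is not None else [None] * len(df))):
            if b == "NEVER":
                mig_idx[i] = MIG_NEVER
            elif y is not None and str(y) != "" and not pd.isna(y):
                mig_idx[i] = 1 + min(int(float(y)), MIG_YEARS_MAX)
            else:
                # bin without a counter: place at the bin's lower edge
                lower = {"MOVED_0_5": 0, "MOVED_6_11": 6, "MOVED_12_PLUS": 12}[b]
                mig_idx[i] = 1 + lower
        np.add.at(
            state.counts,
            (df["age"].to_numpy(int), res_idx.to_numpy(int), edu_idx.to_numpy(int), mig_idx),
            df["count"].to_numpy(float),
        )
        return state

    @classmethod
    def from_csv(cls, path, age_cap: int = DEFAULT_AGE_CAP) -> "PopulationState":
        return cls.from_frame(pd.read_csv(path), age_cap)


def total_population(state: PopulationState, residence: Residence | None = None) -> float:
    """Total persons, optionally restricted to one residence stratum."""
    if residence is None:
        return float(state.counts.sum())
    return float(state.counts[:, int(residence)].sum())


@dataclass
class LifeTable:
    """Period life table built from single-year mortality hazards.

    Attributes
    ----------
    hazards : mortality rate per person-year by age
    lx : survivorship, l(0) = 1
    Lx : person-years lived in each age interval
    ex : remaining life expectancy at each age (years)
    """

    hazards: np.ndarray
    lx: np.ndarray
    Lx: np.ndarray
    ex: np.ndarray

    @property
    def e0(self) -> float:
        return float(self.ex[0])


def build_life_table(hazards: np.ndarray) -> LifeTable:
    """Build a period life table from per-age hazards.

    Survivorship decays as ``l(x+1) = l(x) * exp(-h(x))``; person-years
    use the trapezoid ``L(x) = (l(x) + l(x+1)) / 2``. The table is closed
    at the terminal age with the exponential residual
    ``L = l / h`` (or one person-year per survivor if the terminal
    hazard is zero).
    """
    h = np.asarray(hazards, dtype=float)
    if h.ndim != 1 or h.size < 1:
        raise ValueError("hazards must be a 1-D array with at least one age")
    if np.any(h < 0) or not np.all(np.isfinite(h) | np.isinf(h)):
        raise ValueError("hazards must be non-negative")
    n = h.size
    lx = np.empty(n + 1)
    lx[0] = 1.0
    lx[1:] = np.exp(-np.cumsum(h))
    Lx = np.empty(n)
    Lx[:-1] = 0.5 * (lx[:-2] + lx[1:-1])
    if h[-1] > 0:
        Lx[-1] = lx[-2] / h[-1]
    else:
        Lx[-1] = lx[-2] * 1.0
    # e(x) = person-years above x per survivor at x
    rev_cum = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx[:-1] > 0, rev_cum / lx[:-1], 0.0)
    return LifeTable(hazards=h, lx=lx[:-1], Lx=Lx, ex=ex)
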