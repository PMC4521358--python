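"""Annual transitions other than death: migration and education assignment.

Migration between rural and urban areas is an annual hazard per
direction and education category with a linear secular trend, clamped
to [0, 1].  Educational attainment is assigned once, at birth, from a
residence-specific distribution whose category proportions drift
linearly over birth cohorts (tracking the prevalence among women aged
20-24, the age by which attainment has plateaued); trended proportions
are projected back onto the simplex by truncation at zero and
renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import (
    MIG_NEVER,
    MIG_YEARS_MAX,
    MigrationBin,
    MoveDirection,
    N_EDUCATION,
    N_RESIDENCE,
)

N_DIRECTIONS = 2  # 0 = rural_to_urban, 1 = urban_to_rural
DIR_R2U = 0
DIR_U2R = 1


@dataclass
class MigrationParams:
    """Annual move hazards per direction x education, linearly trended."""

    base_rate: np.ndarray  # (2 directions, 4 education)
    trend: np.ndarray
    reference_year: int

    def __post_init__(self) -> None:
        for name in ("base_rate", "trend"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_DIRECTIONS, N_EDUCATION):
                arr = np.broadcast_to(arr, (N_DIRECTIONS, N_EDUCATION)).copy()
            setattr(self, name, arr)
        if np.any(self.base_rate < 0) or np.any(self.base_rate > 1):
            raise ValueError("base migration rates must lie in [0, 1]")

    @classmethod
    def none(cls, reference_year: int = 0) -> "MigrationParams":
        return cls(np.zeros((N_DIRECTIONS, N_EDUCATION)), np.zeros((N_DIRECTIONS, N_EDUCATION)), reference_year)

    def rates(self, year: int) -> np.ndarray:
        """(direction, education) rates at ``year``, clamped to [0, 1]."""
        return np.clip(self.base_rate + self.trend * (year - self.reference_year), 0.0, 1.0)


def migration_hazard(params: MigrationParams, direction: int, education: int, year: int) -> float:
    """Moves per person-year for one direction/education in one year."""
    if direction not in (DIR_R2U, DIR_U2R):
        raise ValueError("direction must be rural_to_urban (0) or urban_to_rural (1)")
    if not 0 <= education < N_EDUCATION:
        raise ValueError("unknown education category")
    return float(params.rates(year)[direction, education])


@dataclass
class EducationTrendParams:
    """Birth-cohort education distribution per residence with linear drift."""

    baseline: np.ndarray  # (2 residences, 4 categories), rows on the simplex
    trend: np.ndarray  # per-year change per category
    reference_year: int

    def __post_init__(self) -> None:
        for name in ("baseline", "trend"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_RESIDENCE, N_EDUCATION):
                raise ValueError(f"{name} must have shape (2, 4)")
            setattr(self, name, arr)
        if np.any(self.baseline < 0) or np.any(np.abs(self.baseline.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("baseline education proportions must be a distribution per residence")


def newborn_education_distribution(
    params: EducationTrendParams, birth_year: int, residence: int
) -> np.ndarray:
    """Education-category probabilities for a girl born in ``birth_year``.

    Linear drift from the baseline, truncated at zero and renormalized
    so the result is a probability vector.
    """
    raw = params.baseline[residence] + params.trend[residence] * (birth_year - params.reference_year)
    raw = np.maximum(raw, 0.0)
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            f"education trend extrapolation to {birth_year} leaves no probability mass"
        )
    return raw / total


def migration_bin_advance(
    bin: MigrationBin,
    moved_this_year: bool,
    direction: MoveDirection = MoveDirection.NONE,
    years_since_move: int | None = None,
) -> tuple[MigrationBin, MoveDirection, int | None]:
    """Advance one person's migration bookkeeping by one year.

    On a move the person enters the 0-5-year bin with the new
    direction and a reset counter.  Otherwise the years-since-move
    counter ticks and the bin follows it across the 6- and 12-year
    boundaries; never-movers stay put.  Returns
    ``(bin, direction, years_since_move)``.
    """
    if moved_this_year:
        if direction == MoveDirection.NONE:
            raise ValueError("a move requires a direction")
        return MigrationBin.MOVED_0_5, direction, 0
    if bin == MigrationBin.NEVER:
        return MigrationBin.NEVER, MoveDirection.NONE, None
    if years_since_move is None:
        raise ValueError("movers carry a years-since-move counter")
    years = min(years_since_move + 1, MIG_YEARS_MAX)
    if years <= 5:
        new_bin = MigrationBin.MOVED_0_5
    elif years <= 11:
        new_bin = MigrationBin.MOVED_6_11
    else:
        new_bin = MigrationBin.MOVED_12_PLUS
    return new_bin, direction, years


def advance_migration_axis(counts_m: np.ndarray) -> np.ndarray:
    """Shift the internal migration axis of a counts array by one year.

    ``counts_m`` has the migration axis last: index 0 never, index
    ``1+k`` = moved ``k`` years ago with ``k = 12`` absorbing.
    """
    out = np.zeros_like(counts_m)
    out[..., MIG_NEVER] = counts_m[..., MIG_NEVER]
    out[..., 2:] = counts_m[..., 1:-1]
    out[..., -1] += counts_m[..., -1]
    return out
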