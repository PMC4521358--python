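"""Mortality: education decomposition and a Lee-Carter-type surface.

An observed aggregate mortality rate mixes education-specific rates.
With ``p`` the education composition of the group and ``RR`` the
relative risk of death of each attainment category against the
reference (rural women with no schooling),

    mu_agg = mu_ref * sum_e p_e * RR_e          (aggregation)
    mu_ref = mu_agg / sum_e p_e * RR_e          (decomposition)

The reference-category rate itself follows a Lee-Carter-type log-linear
surface per residence and age cluster (infants <1, children 1-10,
adults >10):

    log mu_ref(age, year) = c + beta_year * (year - y0) + beta_age * (age - a0)

where ``y0``/``a0`` are fixed centering constants (simulation start
year and cluster mid-age) that decorrelate the intercept from the
slopes during calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import DEFAULT_AGE_CAP, N_EDUCATION, N_RESIDENCE, Residence

N_CLUSTERS = 3
# Cluster membership by single-year age: 0 = infants (<1), 1 = 1-10, 2 = 11+.
CLUSTER_BOUNDS = ((0, 0), (1, 10), (11, DEFAULT_AGE_CAP))


def cluster_of_age(age) -> np.ndarray:
    age = np.asarray(age)
    return np.where(age < 1, 0, np.where(age <= 10, 1, 2))


def reference_mortality(mu_agg: float, p: np.ndarray, rr: np.ndarray) -> float:
    """Solve the mixture for the reference-category rate.

    ``p`` is the 4-vector of education proportions (must sum to 1),
    ``rr`` the 4-vector of relative risks with ``rr[0]`` the reference
    (conventionally 1).
    """
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if mu_agg < 0:
        raise ValueError("aggregate mortality rate must be non-negative")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("education proportions must be non-negative and sum to 1")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be strictly positive")
    return float(mu_agg / np.dot(p, rr))


def aggregate_mortality(mu_ref: float, p: np.ndarray, rr: np.ndarray) -> float:
    """Mix education-specific rates back into the aggregate rate."""
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if mu_ref < 0:
        raise ValueError("reference mortality rate must be non-negative")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("education proportions must be non-negative and sum to 1")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be strictly positive")
    return float(mu_ref * np.dot(p, rr))


@dataclass
class EducationRR:
    """Relative risk of death per residence x education category.

    The global reference is the rural/no-schooling category, pinned at
    1; all risks must be strictly positive.
    """

    rr: np.ndarray  # (2, 4)

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.shape != (N_RESIDENCE, N_EDUCATION):
            raise ValueError("rr must have shape (2 residences, 4 education categories)")
        if np.any(self.rr <= 0):
            raise ValueError("relative risks must be strictly positive")
        if abs(self.rr[Residence.RURAL, 0] - 1.0) > 1e-12:
            raise ValueError("rural no-schooling category is the reference; rr must be 1")

    @classmethod
    def neutral(cls) -> "EducationRR":
        return cls(rr=np.ones((N_RESIDENCE, N_EDUCATION)))


@dataclass
class LeeCarterParams:
    """Log-linear mortality surface per residence x age cluster.

    ``c``, ``beta_year``, ``beta_age`` have shape (2, 3); centering uses
    one reference year and a per-cluster reference age.
    """

    c: np.ndarray
    beta_year: np.ndarray
    beta_age: np.ndarray
    reference_year: int
    reference_ages: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        for name in ("c", "beta_year", "beta_age"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_RESIDENCE, N_CLUSTERS):
                raise ValueError(f"{name} must have shape (2 residences, 3 clusters)")
            setattr(self, name, arr)
        self.reference_ages = np.asarray(self.reference_ages, dtype=float)
        if self.reference_ages.shape != (N_CLUSTERS,):
            raise ValueError("reference_ages must have length 3")

    @classmethod
    def default_reference_ages(cls, age_cap: int = DEFAULT_AGE_CAP) -> np.ndarray:
        # cluster mid-ages: infant 0, children 5.5, adults mid of 11..cap
        return np.array([0.0, 5.5, (11 + age_cap) / 2.0])


def lee_carter_rate(params: LeeCarterParams, age, year, residence: int, age_cap: int = DEFAULT_AGE_CAP):
    """Reference-category mortality rate from the log-linear surface."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or np.any(age > age_cap):
        raise ValueError(f"age outside [0, {age_cap}]")
    cl = cluster_of_age(age)
    log_mu = (
        params.c[residence, cl]
        + params.beta_year[residence, cl] * (np.asarray(year, float) - params.reference_year)
        + params.beta_age[residence, cl] * (age - params.reference_ages[cl])
    )
    out = np.exp(log_mu)
    return out if out.ndim else float(out)


def mortality_hazard(
    params: LeeCarterParams,
    rr: EducationRR,
    age,
    year,
    residence: int,
    education: int,
    age_cap: int = DEFAULT_AGE_CAP,
):
    """Education-specific hazard: surface rate times the relative risk."""
    return lee_carter_rate(params, age, year, residence, age_cap) * rr.rr[residence, education]


def hazard_schedule(
    params: LeeCarterParams,
    rr: EducationRR,
    year: int,
    age_cap: int = DEFAULT_AGE_CAP,
) -> np.ndarray:
    """Age x residence x education hazard array for one calendar year."""
    ages = np.arange(age_cap + 1, dtype=float)
    cl = cluster_of_age(ages)
    out = np.empty((age_cap + 1, N_RESIDENCE, N_EDUCATION))
    for res in range(N_RESIDENCE):
        base = np.exp(
            params.c[res, cl]
            + params.beta_year[res, cl] * (year - params.reference_year)
            + params.beta_age[res, cl] * (ages - params.reference_ages[cl])
        )
        out[:, res, :] = base[:, None] * rr.rr[res][None, :]
    return out
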