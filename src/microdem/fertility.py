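"""Gompertz-style cumulative fertility curve with a linear secular trend.

Cumulative births per woman up to exact age ``t`` follow the
double-exponential curve

    G(t) = F * (1/2) ** (r ** ((t - a) / b)),   r = ln(0.95) / ln(0.05)

with ``F`` the lifetime quantum (total births per woman), ``a`` the
median age of childbearing (G(a) = F/2), and ``b`` the length of the age
interval over which cumulative fertility rises from 5% to 95% of F.
A linear secular trend acts on the quantum only: the effective quantum
in calendar year ``y`` is ``max(0, F + trend_F * (y - reference_year))``;
the timing parameters ``a`` and ``b`` are held fixed.

Annual age-specific rates are first differences of G, so they telescope
back to the effective quantum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import DEFAULT_AGE_CAP, N_EDUCATION, N_RESIDENCE

# Ratio of logs; base-independent.
R_GOMPERTZ = np.log(0.95) / np.log(0.05)


def gp_cumulative(F, a, b, t):
    """Cumulative births per woman up to exact age ``t``.

    Strictly increasing in ``t``, bounded in (0, F); ``G(a) = F / 2``.
    ``F``, ``a``, ``b`` must be positive.  Vectorized over any argument.
    """
    F = np.asarray(F, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(F <= 0) or np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("gp_cumulative requires F > 0, a > 0, b > 0")
    t = np.asarray(t, dtype=float)
    out = F * 0.5 ** (R_GOMPERTZ ** ((t - a) / b))
    return out if out.ndim else float(out)


@dataclass
class FertilityParams:
    """Fertility curve parameters per residence x education stratum.

    Arrays are shaped ``(2 residences, 4 education categories)``; in the
    simplest model variant all education columns are tied to one value
    per residence.  ``trend_F`` is births/woman per calendar year.
    """

    F: np.ndarray
    a: np.ndarray
    b: np.ndarray
    trend_F: np.ndarray
    reference_year: int

    def __post_init__(self) -> None:
        shape = (N_RESIDENCE, N_EDUCATION)
        for name in ("F", "a", "b", "trend_F"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                arr = np.broadcast_to(arr, shape).copy()
            setattr(self, name, arr)
        if np.any(self.F <= 0) or np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("fertility requires F > 0, a > 0, b > 0 at reference year")

    def effective_F(self, year) -> np.ndarray:
        """Quantum at ``year`` under the linear trend, clamped at 0."""
        return np.maximum(0.0, self.F + self.trend_F * (np.asarray(year, float) - self.reference_year))


def annual_fertility_rate(
    params: FertilityParams,
    age,
    year: int,
    residence: int,
    education: int,
):
    """Births per woman-year at attained ``age`` in calendar ``year``.

    The annual rate is the increment ``G(age + 1) - G(age)`` of the
    cumulative curve evaluated with the trend-adjusted quantum; zero
    when the quantum is clamped to zero.
    """
    F_eff = params.effective_F(year)[residence, education]
    if F_eff <= 0:
        return np.zeros_like(np.asarray(age, dtype=float)) if np.ndim(age) else 0.0
    a = params.a[residence, education]
    b = params.b[residence, education]
    return gp_cumulative(F_eff, a, b, np.asarray(age, float) + 1.0) - gp_cumulative(
        F_eff, a, b, np.asarray(age, float)
    )


def annual_rate_schedule(params: FertilityParams, year: int, age_cap: int = DEFAULT_AGE_CAP) -> np.ndarray:
    """Age x residence x education array of annual fertility rates."""
    ages = np.arange(age_cap + 1, dtype=float)
    F_eff = params.effective_F(year)  # (2, 4)
    out = np.zeros((age_cap + 1, N_RESIDENCE, N_EDUCATION))
    pos = F_eff > 0
    if np.any(pos):
        a = params.a[None, :, :]
        b = params.b[None, :, :]
        Fe = np.where(pos, F_eff, 1.0)[None, :, :]
        t = ages[:, None, None]
        hi = Fe * 0.5 ** (R_GOMPERTZ ** ((t + 1.0 - a) / b))
        lo = Fe * 0.5 ** (R_GOMPERTZ ** ((t - a) / b))
        out = np.where(pos[None, :, :], hi - lo, 0.0)
    return out


def total_fertility_rate(
    params: FertilityParams,
    year: int,
    residence: int,
    education: int,
    age_cap: int = DEFAULT_AGE_CAP,
) -> float:
    """Period TFR: sum of annual rates over all ages (telescopes to F_eff)."""
    ages = np.arange(age_cap + 1)
    return float(np.sum(annual_fertility_rate(params, ages, year, residence, education)))
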