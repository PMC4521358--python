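"""Full parameter set for one model variant, with a flat calibrated view.

Three nested variants share one simulation engine:

* ``v1`` — age and residence only: one fertility curve per residence
  (tied across education categories), the Lee-Carter surface per
  residence, no education effects on mortality (RR = 1), no migration,
  no education-prevalence drift.
* ``v2`` — adds education: fertility per residence x education,
  relative risks of death by education, and linear trends in the
  birth-cohort education distribution.
* ``v3`` — adds rural-to-urban migration rates (per education) and
  their linear trends.

``ParameterSet`` stores the complete structure; a :class:`VariantSpec`
defines which entries are free during calibration and maps them to and
from a named flat vector with bounds (which double as the vague uniform
priors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .fertility import FertilityParams
from .mortality import EducationRR, LeeCarterParams, N_CLUSTERS
from .state import Education, N_EDUCATION, N_RESIDENCE, Residence
from .transitions import DIR_R2U, EducationTrendParams, MigrationParams

VARIANTS = ("v1", "v2", "v3")
_RES_NAMES = ("urban", "rural")
_EDU_NAMES = tuple(e.name for e in Education)
_CLUSTER_NAMES = ("infant", "child", "adult")


@dataclass
class ParameterSet:
    """All demographic parameters for one model variant.

    ``education_intervention_year``, when set, redirects the
    no-schooling share of rural birth cohorts born in or after that
    year into the 1-5-years category (universal primary education).
    """

    variant: str
    fertility: FertilityParams
    lee_carter: LeeCarterParams
    education_rr: EducationRR
    migration: MigrationParams
    education_trend: EducationTrendParams
    education_intervention_year: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            variant=self.variant,
            fertility=replace(
                self.fertility,
                F=self.fertility.F.copy(),
                a=self.fertility.a.copy(),
                b=self.fertility.b.copy(),
                trend_F=self.fertility.trend_F.copy(),
            ),
            lee_carter=replace(
                self.lee_carter,
                c=self.lee_carter.c.copy(),
                beta_year=self.lee_carter.beta_year.copy(),
                beta_age=self.lee_carter.beta_age.copy(),
                reference_ages=self.lee_carter.reference_ages.copy(),
            ),
            education_rr=EducationRR(self.education_rr.rr.copy()),
            migration=replace(
                self.migration,
                base_rate=self.migration.base_rate.copy(),
                trend=self.migration.trend.copy(),
            ),
            education_trend=replace(
                self.education_trend,
                baseline=self.education_trend.baseline.copy(),
                trend=self.education_trend.trend.copy(),
            ),
            education_intervention_year=self.education_intervention_year,
        )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "fertility": {
                "F": self.fertility.F.tolist(),
                "a": self.fertility.a.tolist(),
                "b": self.fertility.b.tolist(),
                "trend_F": self.fertility.trend_F.tolist(),
                "reference_year": self.fertility.reference_year,
            },
            "lee_carter": {
                "c": self.lee_carter.c.tolist(),
                "beta_year": self.lee_carter.beta_year.tolist(),
                "beta_age": self.lee_carter.beta_age.tolist(),
                "reference_year": self.lee_carter.reference_year,
                "reference_ages": self.lee_carter.reference_ages.tolist(),
            },
            "education_rr": {"rr": self.education_rr.rr.tolist()},
            "migration": {
                "base_rate": self.migration.base_rate.tolist(),
                "trend": self.migration.trend.tolist(),
                "reference_year": self.migration.reference_year,
            },
            "education_trend": {
                "baseline": self.education_trend.baseline.tolist(),
                "trend": self.education_trend.trend.tolist(),
                "reference_year": self.education_trend.reference_year,
            },
            "education_intervention_year": self.education_intervention_year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            variant=d["variant"],
            fertility=FertilityParams(**{k: np.asarray(v) if isinstance(v, list) else v for k, v in d["fertility"].items()}),
            lee_carter=LeeCarterParams(**{k: np.asarray(v) if isinstance(v, list) else v for k, v in d["lee_carter"].items()}),
            education_rr=EducationRR(np.asarray(d["education_rr"]["rr"])),
            migration=MigrationParams(**{k: np.asarray(v) if isinstance(v, list) else v for k, v in d["migration"].items()}),
            education_trend=EducationTrendParams(**{k: np.asarray(v) if isinstance(v, list) else v for k, v in d["education_trend"].items()}),
            education_intervention_year=d.get("education_intervention_year"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FreeParameter:
    name: str
    lo: float
    hi: float
    getter: callable
    setter: callable
    block: str


def _fert_entry(field_name, res, edu, lo, hi, tied):
    """Fertility entry; when tied, writing broadcasts across education."""
    def get(ps):
        return getattr(ps.fertility, field_name)[res, edu]

    def set_(ps, v):
        arr = getattr(ps.fertility, field_name)
        if tied:
            arr[res, :] = v
        else:
            arr[res, edu] = v

    return get, set_


class VariantSpec:
    """Free-parameter layout, bounds and blocks for one model variant."""

    def __init__(self, variant: str):
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        self._params: list[FreeParameter] = []
        self._build()

    # bounds double as vague uniform priors
    _FERT_BOUNDS = {"F": (0.05, 10.0), "a": (12.0, 40.0), "b": (1.0, 30.0), "trend_F": (-0.2, 0.2)}
    _LC_BOUNDS = {"c": (-12.0, -0.5), "beta_year": (-0.15, 0.15), "beta_age": (-0.6, 0.6)}
    _RR_BOUNDS = (0.05, 2.0)
    _MIG_BASE_BOUNDS = (0.0, 0.2)
    _MIG_TREND_BOUNDS = (-0.01, 0.01)
    _EDU_TREND_BOUNDS = (-0.05, 0.05)

    def _add(self, name, lo, hi, getter, setter, block):
        self._params.append(FreeParameter(name, lo, hi, getter, setter, block))

    def _build(self) -> None:
        tied = self.variant == "v1"
        edu_iter = (0,) if tied else range(N_EDUCATION)
        for res in range(N_RESIDENCE):
            for edu in edu_iter:
                block = f"fert_{_RES_NAMES[res]}" + ("" if tied else f"_{_EDU_NAMES[edu]}")
                for fld in ("F", "a", "b", "trend_F"):
                    lo, hi = self._FERT_BOUNDS[fld]
                    get, set_ = _fert_entry(fld, res, edu, lo, hi, tied)
                    suffix = "" if tied else f"_{_EDU_NAMES[edu]}"
                    self._add(f"fert_{fld}_{_RES_NAMES[res]}{suffix}", lo, hi, get, set_, block)
        for res in range(N_RESIDENCE):
            for cl in range(N_CLUSTERS):
                block = f"lc_{_RES_NAMES[res]}_{_CLUSTER_NAMES[cl]}"
                fields = ("c", "beta_year") if cl == 0 else ("c", "beta_year", "beta_age")
                for fld in fields:
                    lo, hi = self._LC_BOUNDS[fld]

                    def get(ps, fld=fld, res=res, cl=cl):
                        return getattr(ps.lee_carter, fld)[res, cl]

                    def set_(ps, v, fld=fld, res=res, cl=cl):
                        getattr(ps.lee_carter, fld)[res, cl] = v

                    self._add(f"lc_{fld}_{_RES_NAMES[res]}_{_CLUSTER_NAMES[cl]}", lo, hi, get, set_, block)
        if self.variant in ("v2", "v3"):
            for res in range(N_RESIDENCE):
                for edu in range(N_EDUCATION):
                    if res == Residence.RURAL and edu == 0:
                        continue  # global reference, pinned at 1

                    def get(ps, res=res, edu=edu):
                        return ps.education_rr.rr[res, edu]

                    def set_(ps, v, res=res, edu=edu):
                        ps.education_rr.rr[res, edu] = v

                    lo, hi = self._RR_BOUNDS
                    self._add(f"rr_{_RES_NAMES[res]}_{_EDU_NAMES[edu]}", lo, hi, get, set_, "rr")
            for res in range(N_RESIDENCE):
                for edu in range(N_EDUCATION):

                    def get(ps, res=res, edu=edu):
                        return ps.education_trend.trend[res, edu]

                    def set_(ps, v, res=res, edu=edu):
                        ps.education_trend.trend[res, edu] = v

                    lo, hi = self._EDU_TREND_BOUNDS
                    self._add(
                        f"edutrend_{_RES_NAMES[res]}_{_EDU_NAMES[edu]}",
                        lo,
                        hi,
                        get,
                        set_,
                        f"edutrend_{_RES_NAMES[res]}",
                    )
        if self.variant == "v3":
            for edu in range(N_EDUCATION):

                def get_b(ps, edu=edu):
                    return ps.migration.base_rate[DIR_R2U, edu]

                def set_b(ps, v, edu=edu):
                    ps.migration.base_rate[DIR_R2U, edu] = v

                def get_t(ps, edu=edu):
                    return ps.migration.trend[DIR_R2U, edu]

                def set_t(ps, v, edu=edu):
                    ps.migration.trend[DIR_R2U, edu] = v

                lo, hi = self._MIG_BASE_BOUNDS
                self._add(f"mig_base_{_EDU_NAMES[edu]}", lo, hi, get_b, set_b, f"mig_{_EDU_NAMES[edu]}")
                lo, hi = self._MIG_TREND_BOUNDS
                self._add(f"mig_trend_{_EDU_NAMES[edu]}", lo, hi, get_t, set_t, f"mig_{_EDU_NAMES[edu]}")

    # -- public surface ----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [p.name for p in self._params]

    @property
    def n_params(self) -> int:
        return len(self._params)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([(p.lo, p.hi) for p in self._params])

    @property
    def blocks(self) -> dict[str, np.ndarray]:
        """Parameter-index groups updated jointly during calibration."""
        out: dict[str, list[int]] = {}
        for i, p in enumerate(self._params):
            out.setdefault(p.block, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def to_vector(self, ps: ParameterSet) -> np.ndarray:
        return np.array([p.getter(ps) for p in self._params])

    def from_vector(self, theta: np.ndarray, template: ParameterSet) -> ParameterSet:
        """New ParameterSet: template's fixed structure + free values."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {theta.shape}")
        ps = neutralize(template, self.variant)
        for p, v in zip(self._params, theta):
            p.setter(ps, float(v))
        return ps

    def in_bounds(self, theta: np.ndarray) -> bool:
        b = self.bounds
        return bool(np.all(theta >= b[:, 0]) and np.all(theta <= b[:, 1]))

    def clip_to_bounds(self, theta: np.ndarray) -> np.ndarray:
        b = self.bounds
        return np.clip(theta, b[:, 0], b[:, 1])


def neutralize(template: ParameterSet, variant: str) -> ParameterSet:
    """Copy ``template`` with the structures a variant lacks switched off.

    v1 and v2 carry zero migration; v1 additionally has unit relative
    risks, education-tied fertility and frozen education prevalence.
    """
    ps = template.copy()
    ps.variant = variant
    if variant in ("v1", "v2"):
        ps.migration.base_rate[:] = 0.0
        ps.migration.trend[:] = 0.0
    if variant == "v1":
        ps.education_rr.rr[:] = 1.0
        ps.education_trend.trend[:] = 0.0
        for fld in ("F", "a", "b", "trend_F"):
            arr = getattr(ps.fertility, fld)
            arr[:, :] = arr[:, :1]
    return ps


def default_template(
    variant: str = "v3",
    reference_year: int = 1992,
    baseline_education: np.ndarray | None = None,
    reference_ages: np.ndarray | None = None,
) -> ParameterSet:
    """A mid-range starting structure carrying the fixed metadata.

    The numeric values are placeholders inside the prior bounds; the
    calibration overwrites every free entry.  What matters here are the
    centering constants and the baseline education mix, which are fixed
    inputs rather than calibrated parameters.
    """
    if baseline_education is None:
        baseline_education = np.array([[0.25, 0.25, 0.40, 0.10], [0.55, 0.25, 0.17, 0.03]])
    if reference_ages is None:
        reference_ages = LeeCarterParams.default_reference_ages()
    ps = ParameterSet(
        variant=variant,
        fertility=FertilityParams(
            F=np.full((2, 4), 3.5),
            a=np.full((2, 4), 23.0),
            b=np.full((2, 4), 10.0),
            trend_F=np.zeros((2, 4)),
            reference_year=reference_year,
        ),
        lee_carter=LeeCarterParams(
            c=np.array([[-3.5, -6.0, -5.5], [-3.0, -5.5, -5.0]]),
            beta_year=np.zeros((2, 3)),
            beta_age=np.array([[0.0, -0.1, 0.09], [0.0, -0.1, 0.09]]),
            reference_year=reference_year,
            reference_ages=reference_ages,
        ),
        education_rr=EducationRR.neutral(),
        migration=MigrationParams.none(reference_year),
        education_trend=EducationTrendParams(
            baseline=baseline_education,
            trend=np.zeros((2, 4)),
            reference_year=reference_year,
        ),
    )
    return neutralize(ps, variant)
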