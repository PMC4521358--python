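"""Calibration targets and the Gaussian likelihood / deviance.

Targets mirror five survey-style data classes — children ever born by
maternal age band, probability of death by year and age band, education
prevalence at ages 20-24, migration lookback proportions (moved within
6 years / 12 years / ever), and population size by year and residence —
plus annual life-expectancy rows kept out of the likelihood and used
only for external validation.

Each target row carries a point estimate with a 95% interval; the
likelihood treats rows as independent Normals with standard deviation
``(ci_high - ci_low) / 3.92``, floored to avoid degenerate zero-width
intervals dominating the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TARGET_CLASSES = (
    "fertility",
    "mortality",
    "education",
    "migration",
    "population_size",
    "life_expectancy_validation",
)

COLUMNS = [
    "class",
    "year",
    "age_low",
    "age_high",
    "residence",
    "education",
    "window",
    "estimate",
    "ci_low",
    "ci_high",
    "calibration",
]

# Normal 95% interval spans 2 * 1.96 standard deviations.
CI_TO_SD = 3.92


@dataclass
class Target:
    """One calibration or validation row."""

    cls: str
    year: int
    estimate: float
    ci_low: float
    ci_high: float
    age_low: int | None = None
    age_high: int | None = None
    residence: str = "all"
    education: str = "all"
    window: str = ""
    calibration: bool = True


class TargetSet:
    """Ordered collection of targets backed by a DataFrame.

    ``sigma`` is precomputed from the intervals with a floor of
    ``max(sigma_floor_rel * |estimate|, sigma_floor_abs)``.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        sigma_floor_rel: float = 0.01,
        sigma_floor_abs: float = 1e-9,
    ):
        df = df.copy().reset_index(drop=True)
        for col in COLUMNS:
            if col not in df.columns:
                if col == "calibration":
                    df[col] = df["class"] != "life_expectancy_validation"
                elif col in ("residence", "education"):
                    df[col] = "all"
                elif col == "window":
                    df[col] = ""
                else:
                    raise ValueError(f"target table missing column {col!r}")
        self._validate(df)
        df["calibration"] = df["calibration"].astype(bool)
        # validation-only class never enters the likelihood
        df.loc[df["class"] == "life_expectancy_validation", "calibration"] = False
        sigma = (df["ci_high"] - df["ci_low"]).to_numpy(float) / CI_TO_SD
        floor = np.maximum(sigma_floor_rel * np.abs(df["estimate"].to_numpy(float)), sigma_floor_abs)
        df["sigma"] = np.maximum(sigma, floor)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        problems = []
        for i, row in df.iterrows():
            if row["class"] not in TARGET_CLASSES:
                problems.append(f"row {i}: unknown target class {row['class']!r}")
                continue
            if not (row["ci_low"] <= row["estimate"] <= row["ci_high"]):
                problems.append(
                    f"row {i}: interval inversion ci_low={row['ci_low']} "
                    f"estimate={row['estimate']} ci_high={row['ci_high']}"
                )
            if row["class"] == "population_size" and row["estimate"] <= 0:
                problems.append(f"row {i}: population size must be positive")
        # per survey-group education prevalences must not exceed the simplex
        edu = df[df["class"] == "education"]
        if len(edu) and not problems:
            sums = edu.groupby(["year", "residence"])["estimate"].sum()
            bad = sums[(sums < 0) | (sums > 1.0 + 1e-6)]
            for key, s in bad.items():
                problems.append(f"education prevalences for {key} sum to {s:.4f} > 1")
        if problems:
            raise ValueError("invalid target rows:\n" + "\n".join(problems))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def calibration_mask(self) -> np.ndarray:
        return self.df["calibration"].to_numpy(bool)

    def subset(self, cls: str) -> pd.DataFrame:
        return self.df[self.df["class"] == cls]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.drop(columns=["sigma"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "TargetSet":
        df = pd.read_csv(path, keep_default_na=True)
        if len(df) == 0:
            return cls(pd.DataFrame(columns=COLUMNS))
        df["window"] = df.get("window", pd.Series([""] * len(df))).fillna("")
        return cls(df, **kw)

    def write_manifest(self, out_dir) -> Path:
        """Write one CSV per target class plus a YAML manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        for tcls in TARGET_CLASSES:
            sub = self.subset(tcls)
            if len(sub) == 0:
                continue
            fname = f"targets_{tcls}.csv"
            sub.drop(columns=["sigma"]).to_csv(out_dir / fname, index=False)
            files.append(
                {"class": tcls, "path": fname, "calibration": bool(sub["calibration"].any())}
            )
        manifest = out_dir / "manifest.yaml"
        with open(manifest, "w") as fh:
            yaml.safe_dump({"targets": files}, fh)
        return manifest


def load_targets(path) -> TargetSet:
    """Load a TargetSet from a YAML manifest or a single combined CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"targets file not found: {path}")
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            manifest = yaml.safe_load(fh) or {}
        frames = []
        for entry in manifest.get("targets", []):
            sub = pd.read_csv(path.parent / entry["path"])
            sub["class"] = entry["class"]
            if "calibration" in entry and "calibration" not in sub.columns:
                sub["calibration"] = entry["calibration"]
            frames.append(sub)
        if not frames:
            return TargetSet(pd.DataFrame(columns=COLUMNS))
        df = pd.concat(frames, ignore_index=True)
        df["window"] = df.get("window", pd.Series([""] * len(df))).fillna("")
        return TargetSet(df)
    return TargetSet.from_csv(path)


def log_likelihood(values, targets: TargetSet) -> float:
    """Sum of Normal log-densities over calibration rows.

    ``values`` is an array of model predictions aligned one-to-one with
    the target rows (validation rows may hold any finite value; they
    are excluded).
    """
    values = np.asarray(getattr(values, "values", values), dtype=float)
    if values.shape != (len(targets),):
        raise ValueError(
            f"model values shape {values.shape} does not match {len(targets)} targets"
        )
    mask = targets.calibration_mask
    est = targets.df["estimate"].to_numpy(float)[mask]
    sig = targets.df["sigma"].to_numpy(float)[mask]
    v = values[mask]
    z = (est - v) / sig
    return float(np.sum(-0.5 * z * z - np.log(sig) - 0.5 * math.log(2.0 * math.pi)))


def deviance(loglik: float) -> float:
    """Deviance, -2 times the log-likelihood."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    return -2.0 * loglik
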