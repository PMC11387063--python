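"""Construction of derived covariates.

Body condition is the residual of an ordinary least-squares regression of
body mass on structural size (wing length), time of day of capture and sex,
fitted separately for the incubation and brood-rearing captures.  Prey
availability is the activity-density index of each foraging habitat type
weighted by the area of that habitat within the foraging radius.  Experience
distinguishes first-time breeders (0) from birds with at least one previous
breeding attempt (1).  All continuous covariates are centred and scaled
before entering a linear predictor, and candidate covariates are screened
pairwise for collinearity (|Pearson r| >= 0.7 flags a pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from owlpath.exceptions import (
    ConstantCovariateError,
    DataError,
    DegenerateDesignError,
    SchemaError,
)

HABITAT_TYPES = ("crop_rotation", "grassland", "border", "biodiversity")

CORRELATION_THRESHOLD = 0.7


@dataclass
class ConditionObservation:
    """One capture of one adult: mass plus the size/time/sex correctors."""

    mass: float
    wing_length: float
    time_of_day: float
    sex: str
    period: str  # "incubation" or "rearing"

    def validate(self) -> None:
        if not self.mass > 0:
            raise DataError(f"mass must be positive, got {self.mass}")
        if not self.wing_length > 0:
            raise DataError(f"wing_length must be positive, got {self.wing_length}")
        if not 0 <= self.time_of_day < 24:
            raise DataError(f"time_of_day must lie in [0, 24), got {self.time_of_day}")
        if self.sex not in ("F", "M"):
            raise DataError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.period not in ("incubation", "rearing"):
            raise DataError(f"period must be 'incubation' or 'rearing', got {self.period!r}")


@dataclass
class PreyInput:
    """Activity-density index and habitat area for one habitat type."""

    habitat_type: str
    index_value: float
    area: float

    def validate(self) -> None:
        if self.habitat_type not in HABITAT_TYPES:
            raise SchemaError(f"unknown habitat_type {self.habitat_type!r}")
        if self.area < 0:
            raise DataError(f"area must be non-negative, got {self.area}")


def compute_body_condition(observations: list[ConditionObservation]) -> np.ndarray:
    """OLS mass residuals per observation, fitted separately per period.

    Returns residuals (grams) in input order.  Within each period's fit the
    residuals sum to zero by the normal equations.
    """
    for obs in observations:
        obs.validate()
    periods = np.array([o.period for o in observations])
    residuals = np.full(len(observations), np.nan)
    for period in ("incubation", "rearing"):
        idx = np.flatnonzero(periods == period)
        if idx.size == 0:
            continue
        if idx.size < 4:
            raise DegenerateDesignError(
                f"period {period!r}: need >= 4 observations to fit 4 regression "
                f"parameters, got {idx.size}"
            )
        sub = [observations[i] for i in idx]
        X = np.column_stack(
            [
                np.ones(len(sub)),
                [o.wing_length for o in sub],
                [o.time_of_day for o in sub],
                [1.0 if o.sex == "M" else 0.0 for o in sub],
            ]
        )
        y = np.array([o.mass for o in sub])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDesignError(
                f"period {period!r}: rank-deficient design (constant wing length "
                "or single sex)"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        residuals[idx] = y - X @ beta
    return residuals


def compute_prey_availability(inputs: list[PreyInput]) -> float:
    """Sum of index x area over the four habitat types (one input each)."""
    for p in inputs:
        p.validate()
    seen = [p.habitat_type for p in inputs]
    if sorted(seen) != sorted(HABITAT_TYPES):
        missing = set(HABITAT_TYPES) - set(seen)
        extra = set(seen) - set(HABITAT_TYPES)
        raise SchemaError(
            f"expected exactly one input per habitat type; missing={sorted(missing)}, "
            f"duplicated_or_extra={sorted(extra) or [h for h in seen if seen.count(h) > 1]}"
        )
    return float(sum(p.index_value * p.area for p in inputs))


def encode_experience(breeding_years: list[int]) -> dict[int, int]:
    """Experience code per year: 0 in the first attempt year, 1 afterwards.

    The returned mapping covers every year from the first to the last attempt
    (gap years after the first attempt are experienced years too).
    """
    if not breeding_years:
        return {}
    if list(breeding_years) != sorted(breeding_years):
        raise DataError("breeding_years must be sorted ascending")
    first, last = breeding_years[0], breeding_years[-1]
    return {year: (0 if year == first else 1) for year in range(first, last + 1)}


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Z-score non-missing entries; returns (z, mean, sd).

    Missing entries (NaN) stay NaN.  The sd uses the n-1 denominator.  The
    (mean, sd) pair is returned so latent values can be imputed on the same
    scale.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ConstantCovariateError(
            f"need >= 2 non-missing values to standardize, got {obs.size}"
        )
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise ConstantCovariateError("covariate has zero spread")
    return (x - mean) / sd, mean, sd


def prepare_covariates(data_dir, out_dir=None):
    """Standardize a dataset's covariate columns for modelling.

    Reads ``annual.csv`` / ``individuals.csv`` from ``data_dir``, z-scores
    every continuous model covariate (missing cells stay missing) and, when
    ``out_dir`` is given, writes ``covariates_prepared.csv`` plus a
    ``scaling.yaml`` with the (mean, sd) pair of each covariate so latent
    values can be imputed on the same scale.  Returns (prepared annual
    table, scaling dict).
    """
    from pathlib import Path

    import yaml

    from owlpath.synthetic_data import ANNUAL_COVARIATES, read_dataset

    ds = read_dataset(data_dir)
    prepared = ds.annual.copy()
    scaling: dict[str, dict[str, float]] = {}
    for col in ANNUAL_COVARIATES:
        z, mean, sd = standardize(prepared[col].to_numpy(dtype=float))
        prepared[col] = z
        scaling[col] = {"mean": mean, "sd": sd}
    spot = ds.individuals["spot_diameter_mm"].to_numpy(dtype=float)
    z, mean, sd = standardize(spot)
    scaling["spot"] = {"mean": mean, "sd": sd}
    prepared.insert(len(prepared.columns), "spot",
                    pd.Series(z, index=ds.individuals["id"]).loc[prepared["id"]].to_numpy())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prepared.to_csv(out / "covariates_prepared.csv", index=False)
        with open(out / "scaling.yaml", "w") as fh:
            yaml.safe_dump(scaling, fh, sort_keys=True)
    return prepared, scaling


def screen_correlations(
    covariates: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> list[tuple[str, str, float]]:
    """Flag covariate pairs with |Pearson r| >= threshold.

    Correlations use pairwise-complete observations (>= 3 complete rows per
    pair).  Flagged pairs are reported, never auto-dropped.
    """
    corr = covariates.corr(method="pearson", min_periods=3)
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return flagged
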