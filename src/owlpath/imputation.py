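"""Latent treatment of missing covariates and unobserved reproduction.

Missing covariate cells are modelled as draws from a normal distribution
whose mean and standard deviation are shared within a grouping appropriate
to the covariate: population-wide, sex-specific, year-specific (prey
availability, which all birds experience together), or individual-specific
(spot diameter, a repeatable trait).  Group means and standard deviations
are themselves parameters with weakly informative priors, estimated from the
observed members of the group; a group with no observed member falls back to
the population level.  Everything operates on the standardized scale
established by the covariate preparation step.

Unobserved reproduction components are latent draws from the fecundity
chain itself (Poisson eggs, then the two binomial stages) given the current
parameters and covariates; observed components truncate the latent ones
(an observed nestling count N forces latent eggs E >= N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from owlpath.exceptions import ConfigurationError, DataError, ImputationError

GROUPINGS = ("population", "sex", "year", "individual")

# Grouping per model covariate; prey availability is population-within-year,
# spot diameter is an individual trait, the rest vary by sex.
DEFAULT_GROUPINGS: dict[str, str] = {
    "laying_date": "sex",
    "cond_incubation": "sex",
    "cond_rearing": "sex",
    "gc_baseline": "sex",
    "gc_stress": "sex",
    "spot": "individual",
    "prey_sm_prelay": "year",
    "prey_vole_prelay": "year",
    "prey_sm_incub": "year",
    "prey_vole_incub": "year",
    "prey_sm_rear": "year",
    "prey_vole_rear": "year",
    "prey_sm_winter": "year",
    "prey_vole_winter": "year",
}


@dataclass
class ImputationSpec:
    """Grouping and priors of the covariate imputation layer.

    ``mean_prior_scale`` is the sd of the normal prior on each group mean;
    ``sd_prior_scale`` the scale of the half-normal prior on each group sd.
    Both act on the z-scored covariate scale.
    """

    groupings: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPINGS))
    mean_prior_scale: float = 10.0
    sd_prior_scale: float = 1.0

    def validate(self) -> None:
        for cov, g in self.groupings.items():
            if g not in GROUPINGS:
                raise ConfigurationError(
                    f"groupings[{cov!r}] must be one of {GROUPINGS}, got {g!r}"
                )
        if self.mean_prior_scale <= 0 or self.sd_prior_scale <= 0:
            raise ConfigurationError("prior scales must be positive")

    def grouping(self, covariate: str) -> str:
        return self.groupings.get(covariate, "population")


def group_labels(
    grouping: str,
    annual: pd.DataFrame,
    individuals: pd.DataFrame,
) -> np.ndarray:
    """Integer group label per annual record for the requested grouping."""
    if grouping == "population":
        return np.zeros(len(annual), dtype=int)
    if grouping == "year":
        return annual["occasion"].to_numpy(dtype=int)
    sex_by_id = individuals.set_index("id")["sex"]
    if grouping == "sex":
        sex = sex_by_id.loc[annual["id"]].to_numpy()
        return (sex == "M").astype(int)
    if grouping == "individual":
        return annual["id"].to_numpy(dtype=int)
    raise ConfigurationError(f"unknown grouping {grouping!r}")


@dataclass
class GroupMoments:
    """Per-missing-cell imputation distribution plus the group estimates."""

    cell_mean: np.ndarray
    cell_sd: np.ndarray
    group_ids: np.ndarray
    group_mean: dict[int, float]
    group_sd: dict[int, float]


def impute_covariate(
    values,
    spec: ImputationSpec,
    labels,
) -> GroupMoments:
    """Normal imputation distribution for each missing cell of one covariate.

    Group means and sds are estimated from the observed members; a group with
    no observed member, or a single member (undefined sd), falls back to the
    population mean/sd.  Values are expected on the z-scored scale.
    """
    spec.validate()
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if x.shape != labels.shape:
        raise DataError("values and labels must have equal length")
    obs = ~np.isnan(x)
    if not obs.any():
        raise ImputationError("no observed values at all; cannot anchor imputation")
    pop_mean = float(x[obs].mean())
    pop_sd = float(x[obs].std(ddof=1)) if obs.sum() > 1 else 1.0
    if pop_sd == 0.0:
        pop_sd = 1.0

    group_mean: dict[int, float] = {}
    group_sd: dict[int, float] = {}
    for g in np.unique(labels):
        sel = obs & (labels == g)
        n_obs = int(sel.sum())
        if n_obs == 0:
            group_mean[g] = pop_mean
            group_sd[g] = pop_sd
        elif n_obs == 1:
            group_mean[g] = float(x[sel][0])
            group_sd[g] = pop_sd
        else:
            group_mean[g] = float(x[sel].mean())
            sd = float(x[sel].std(ddof=1))
            group_sd[g] = sd if sd > 0 else pop_sd

    missing = np.flatnonzero(~obs)
    cell_mean = np.array([group_mean[labels[i]] for i in missing])
    cell_sd = np.array([group_sd[labels[i]] for i in missing])
    return GroupMoments(
        cell_mean=cell_mean,
        cell_sd=cell_sd,
        group_ids=labels[missing],
        group_mean=group_mean,
        group_sd=group_sd,
    )


def sample_latent_reproduction(
    eggs,
    nestlings,
    fledglings,
    psi: float,
    rho_hatch: float,
    rho_fledge: float,
    rng: np.random.Generator,
    n_draws: int = 1,
    max_tries: int = 100_000,
) -> np.ndarray:
    """Draw latent (E, N, F) from the fecundity chain given observed components.

    Missing components (None) are drawn from the chain
    E ~ Poisson(psi), N ~ Binomial(E, rho_hatch), F ~ Binomial(N, rho_fledge);
    observed components condition the draw (rejection sampling), e.g. an
    observed nestling count N truncates latent eggs to E >= N.  Returns an
    (n_draws, 3) integer array.
    """
    obs = (eggs, nestlings, fledglings)
    if all(v is not None for v in obs):
        trip = np.array(obs, dtype=int)
        if not (0 <= trip[2] <= trip[1] <= trip[0]):
            raise DataError("observed reproduction violates 0 <= F <= N <= E")
        return np.tile(trip, (n_draws, 1))
    out = np.empty((n_draws, 3), dtype=int)
    k = 0
    for _ in range(max_tries):
        if k == n_draws:
            break
        E = int(eggs) if eggs is not None else int(rng.poisson(psi))
        N = int(nestlings) if nestlings is not None else int(rng.binomial(E, rho_hatch))
        F = int(fledglings) if fledglings is not None else int(rng.binomial(N, rho_fledge))
        if 0 <= F <= N <= E:
            out[k] = (E, N, F)
            k += 1
    if k < n_draws:
        raise ImputationError("rejection sampling failed: observed values are too improbable")
    return out


def latent_reproduction_init(
    eggs, nestlings, fledglings, typical_eggs: float = 6.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chain-consistent starting values for latent E, N, F.

    Observed components are kept; missing ones are filled so that
    0 <= F <= N <= E holds, anchored at a typical annual egg number.
    Observed values that already violate the chain raise a data error.
    """
    E = np.asarray(eggs, dtype=float).copy()
    N = np.asarray(nestlings, dtype=float).copy()
    F = np.asarray(fledglings, dtype=float).copy()
    obs_E, obs_N, obs_F = ~np.isnan(E), ~np.isnan(N), ~np.isnan(F)

    both = obs_E & obs_N
    if np.any(E[both] < N[both]):
        raise DataError("observed nestlings exceed observed eggs")
    both = obs_N & obs_F
    if np.any(N[both] < F[both]):
        raise DataError("observed fledglings exceed observed nestlings")

    F = np.where(obs_F, F, 0.0)
    lower_N = np.maximum(F, 0.0)
    N = np.where(obs_N, N, np.maximum(np.round(0.8 * typical_eggs), lower_N))
    lower_E = np.maximum(N, 0.0)
    E = np.where(obs_E, E, np.maximum(np.round(typical_eggs), lower_E))
    # Re-clip latent middle components against observed outer ones.
    N = np.where(obs_N, N, np.minimum(N, E))
    N = np.maximum(N, F)
    if np.any(F > N) or np.any(N > E):
        raise DataError("could not initialize a chain-consistent latent state")
    return E.astype(int), N.astype(int), F.astype(int)
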