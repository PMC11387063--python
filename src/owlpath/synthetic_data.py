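"""Synthetic individual-by-year datasets with the structure the model assumes.

The generator emulates a four-breeding-season study of adult barn owls with a
final spring resight occasion: each individual enters at its first breeding
attempt, contributes annual covariates (laying date, body condition at two
time points, glucocorticoid concentrations, plumage spot diameter, seasonal
prey-availability indices), an annual reproduction chain E >= N >= F, and an
encounter history over the occasions.  Two detection groups (ring-only and
VHF-transmitter birds) differ in recapture and dead-recovery probability.

Reproduction is generated at the level of ANNUAL sums, not individual
broods; a configurable shift on the log egg rate
(``second_brood_logit_shift``) inflates annual totals the way
double-brooding years do.  Egg counts are plain Poisson (not
zero-truncated); a zero represents a year without eggs.  Covariate
missingness is missing-completely-at-random, while reproduction is missing
exactly in the years the individual was not captured alive - the
detection-driven mechanism of a real monitoring study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from owlpath import fecundity
from owlpath.exceptions import ConfigurationError
from owlpath.params import (
    DetectionParameters,
    EggModelCoefficients,
    FledgeModelCoefficients,
    HatchModelCoefficients,
    ModelParameters,
    SurvivalCoefficients,
)
from owlpath.survival_mrr import EncounterHistory, detection_arrays, survival_prob

# Natural-unit location/scale per covariate: day-of-year for laying date,
# grams (residual condition), ng/ml (glucocorticoids), millimetres (spot
# diameter), index x area units (prey availability).
DEFAULT_COVARIATE_MEANS_SDS: dict[str, tuple[float, float]] = {
    "laying_date": (100.0, 20.0),
    "cond_incubation": (0.0, 25.0),
    "cond_rearing": (0.0, 25.0),
    "gc_baseline": (10.0, 4.0),
    "gc_stress": (60.0, 18.0),
    "spot": (12.0, 4.0),
    "prey_sm_prelay": (50.0, 15.0),
    "prey_vole_prelay": (50.0, 15.0),
    "prey_sm_incub": (50.0, 15.0),
    "prey_vole_incub": (50.0, 15.0),
    "prey_sm_rear": (50.0, 15.0),
    "prey_vole_rear": (50.0, 15.0),
    "prey_sm_winter": (50.0, 15.0),
    "prey_vole_winter": (50.0, 15.0),
}

# MCAR rates: laying date and spot are near-complete field measurements,
# condition requires repeated captures, blood sampling succeeds less often,
# and prey indices are environmental (always available).
DEFAULT_MISSINGNESS_RATES: dict[str, float] = {
    "laying_date": 0.05,
    "cond_incubation": 0.15,
    "cond_rearing": 0.15,
    "gc_baseline": 0.25,
    "gc_stress": 0.25,
    "spot": 0.05,
    "prey_sm_prelay": 0.0,
    "prey_vole_prelay": 0.0,
    "prey_sm_incub": 0.0,
    "prey_vole_incub": 0.0,
    "prey_sm_rear": 0.0,
    "prey_vole_rear": 0.0,
    "prey_sm_winter": 0.0,
    "prey_vole_winter": 0.0,
}

PREY_COLUMNS = tuple(c for c in DEFAULT_COVARIATE_MEANS_SDS if c.startswith("prey_"))
ANNUAL_COVARIATES = (
    "laying_date",
    "cond_incubation",
    "cond_rearing",
    "gc_baseline",
    "gc_stress",
) + PREY_COLUMNS

# annual.csv column name per model covariate term.
ANNUAL_CSV_COLUMNS: dict[str, str] = {
    "laying_date": "laying_date_doy",
    "cond_incubation": "cond_incubation_g",
    "cond_rearing": "cond_rearing_g",
    "gc_baseline": "gc_baseline_ng_ml",
    "gc_stress": "gc_stress_ng_ml",
    **{c: c for c in PREY_COLUMNS},
}


def default_parameters() -> ModelParameters:
    """Default generating parameters.

    Slopes represent effect sizes typical of an intensively monitored
    European barn owl population: earlier laying and richer pre-laying prey
    raise annual egg numbers; larger annual clutches hatch at lower per-egg
    rates; more offspring raise female survival but cost males; experience,
    plumage spot diameter and winter vole availability act on survival.
    Intercepts correspond to ~6 eggs/year, 80% hatching, 80% fledging and
    70% annual survival at average covariates.
    """
    return ModelParameters(
        egg={
            "F": EggModelCoefficients(
                intercept=float(np.log(6.0)),
                b_experience=0.06,
                b_laying_date=-0.24,
                b_prey_sm_prelay=0.09,
                b_prey_vole_prelay=-0.04,
            ),
            "M": EggModelCoefficients(
                intercept=float(np.log(6.0)),
                b_experience=-0.06,
                b_laying_date=-0.10,
                b_prey_sm_prelay=0.06,
                b_prey_vole_prelay=-0.02,
            ),
        },
        hatch={
            "F": HatchModelCoefficients(
                intercept=float(np.log(0.8 / 0.2)),
                b_experience=0.15,
                b_eggs=-0.48,
                b_laying_date=-0.39,
                b_cond_incubation=0.23,
                b_prey_sm_incub=0.0,
                b_prey_vole_incub=0.22,
            ),
            "M": HatchModelCoefficients(
                intercept=float(np.log(0.8 / 0.2)),
                b_experience=0.18,
                b_eggs=-0.32,
                b_laying_date=0.0,
                b_cond_incubation=0.35,
                b_prey_sm_incub=0.0,
                b_prey_vole_incub=0.09,
            ),
        },
        fledge={
            "F": FledgeModelCoefficients(
                intercept=float(np.log(0.8 / 0.2)),
                b_experience=0.0,
                b_nestlings=-0.20,
                b_laying_date=0.0,
                b_cond_rearing=0.10,
                b_prey_sm_rear=0.0,
                b_prey_vole_rear=0.0,
            ),
            "M": FledgeModelCoefficients(
                intercept=float(np.log(0.8 / 0.2)),
                b_experience=0.0,
                b_nestlings=-0.20,
                b_laying_date=0.0,
                b_cond_rearing=-0.15,
                b_prey_sm_rear=0.0,
                b_prey_vole_rear=0.0,
            ),
        },
        survival={
            "F": SurvivalCoefficients(
                intercept=float(np.log(0.7 / 0.3)),
                b_experience=0.0,
                b_cond_rearing=0.0,
                b_nestlings=0.0,
                b_fledglings=0.44,
                b_gc_baseline=-0.20,
                b_gc_stress=0.0,
                b_spot=0.25,
                b_prey_sm_incub=0.28,
                b_prey_vole_incub=0.0,
                b_prey_sm_winter=0.0,
                b_prey_vole_winter=0.0,
            ),
            "M": SurvivalCoefficients(
                intercept=float(np.log(0.7 / 0.3)),
                b_experience=0.71,
                b_cond_rearing=0.0,
                b_nestlings=-0.32,
                b_fledglings=0.0,
                b_gc_baseline=0.0,
                b_gc_stress=0.0,
                b_spot=0.31,
                b_prey_sm_incub=0.0,
                b_prey_vole_incub=-0.43,
                b_prey_sm_winter=0.0,
                b_prey_vole_winter=0.50,
            ),
        },
        detection=DetectionParameters(),
    )


@dataclass
class SimulationConfig:
    """Shape and generating truth of a synthetic study.

    Defaults mirror the emulated field design: 556 adults over 5 occasions
    (4 breeding seasons plus a final spring resight), 299/556 females and
    237/556 VHF-tagged birds.
    """

    n_individuals: int = 556
    n_occasions: int = 5
    sex_ratio: float = 299.0 / 556.0  # proportion female
    prop_tagged: float = 237.0 / 556.0  # proportion in the VHF group
    true_params: ModelParameters = field(default_factory=default_parameters)
    covariate_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MEANS_SDS)
    )
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_RATES)
    )
    second_brood_logit_shift: float = 0.0
    first_year_entry_weight: float = 0.44  # share of individuals entering in year 0
    prey_year_share: float = 0.5  # share of prey variance common to a year
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_occasions < 2:
            raise ConfigurationError("n_occasions must be >= 2")
        for name in ("sex_ratio", "prop_tagged", "first_year_entry_weight", "prey_year_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for cov, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness_rates[{cov!r}] must lie in [0, 1], got {rate}")
        for cov, (mean, sd) in self.covariate_means_sds.items():
            if not np.isfinite(mean) or not (np.isfinite(sd) and sd > 0):
                raise ConfigurationError(f"covariate_means_sds[{cov!r}] needs finite mean and sd > 0")
        missing = set(DEFAULT_COVARIATE_MEANS_SDS) - set(self.covariate_means_sds)
        if missing:
            raise ConfigurationError(f"covariate_means_sds missing entries for {sorted(missing)}")
        if not np.isfinite(self.second_brood_logit_shift):
            raise ConfigurationError("second_brood_logit_shift must be finite")
        self.true_params.validate()

    @property
    def n_breeding_years(self) -> int:
        return self.n_occasions - 1


@dataclass
class IndividualRecord:
    """One owl: identity, trait covariates, annual records, encounter history."""

    id: int
    sex: str
    tag_group: str
    first_occasion: int
    spot_diameter_mm: float
    annual: pd.DataFrame  # this individual's rows of the annual table
    encounter: EncounterHistory


@dataclass
class SimulatedDataset:
    """Generated tables plus the generating truth.

    ``annual`` contains one row per individual-year in which the bird was
    alive, with missingness applied; ``annual_complete`` retains the
    pre-missingness values for recovery checks.
    """

    individuals: pd.DataFrame
    annual: pd.DataFrame
    encounters: pd.DataFrame
    truth: ModelParameters
    seed: int
    annual_complete: pd.DataFrame | None = None
    individuals_complete: pd.DataFrame | None = None

    def individual_records(self):
        """Yield one validated :class:`IndividualRecord` per individual."""
        occ_cols = sorted(
            (c for c in self.encounters.columns if c.startswith("occ_")),
            key=lambda c: int(c.split("_")[1]),
        )
        enc = self.encounters.set_index("id")
        for _, row in self.individuals.iterrows():
            codes = tuple(int(v) for v in enc.loc[row["id"], occ_cols])
            yield IndividualRecord(
                id=int(row["id"]),
                sex=row["sex"],
                tag_group=row["tag_group"],
                first_occasion=int(row["first_occasion"]),
                spot_diameter_mm=float(row["spot_diameter_mm"]),
                annual=self.annual[self.annual["id"] == row["id"]],
                encounter=EncounterHistory(int(row["first_occasion"]), codes),
            )


def generate_covariates(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the individual table and the complete individual-year covariates.

    Spot diameter is an individual-constant trait; prey availability shares a
    year-level component across individuals; laying date, condition and
    glucocorticoids are drawn independently per individual-year.  Experience
    is deterministic: 0 in the entry year, 1 afterwards.
    """
    config.validate()
    n = config.n_individuals
    n_years = config.n_breeding_years

    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    group = np.where(rng.random(n) < config.prop_tagged, "vhf", "ring")
    if n_years == 1:
        first = np.zeros(n, dtype=int)
    else:
        w0 = config.first_year_entry_weight
        weights = np.full(n_years, (1.0 - w0) / (n_years - 1))
        weights[0] = w0
        first = rng.choice(n_years, size=n, p=weights)
    spot_mean, spot_sd = config.covariate_means_sds["spot"]
    spot = rng.normal(spot_mean, spot_sd, size=n)

    individuals = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "tag_group": group,
            "first_occasion": first,
            "spot_diameter_mm": spot,
        }
    )

    # Year-level prey component shared by all individuals in a year.
    prey_year = {
        cov: rng.normal(0.0, 1.0, size=n_years) for cov in PREY_COLUMNS
    }

    rows_id, rows_year = [], []
    for i in range(n):
        years = np.arange(first[i], n_years)
        rows_id.append(np.full(years.size, i))
        rows_year.append(years)
    rec_id = np.concatenate(rows_id)
    rec_year = np.concatenate(rows_year)
    n_rec = rec_id.size

    annual = pd.DataFrame({"id": rec_id, "occasion": rec_year})
    annual["experience"] = (rec_year > first[rec_id]).astype(int)
    for cov in ("laying_date", "cond_incubation", "cond_rearing", "gc_baseline", "gc_stress"):
        mean, sd = config.covariate_means_sds[cov]
        annual[cov] = rng.normal(mean, sd, size=n_rec)
    share = config.prey_year_share
    for cov in PREY_COLUMNS:
        mean, sd = config.covariate_means_sds[cov]
        year_part = prey_year[cov][rec_year] * np.sqrt(share)
        noise = rng.normal(0.0, 1.0, size=n_rec) * np.sqrt(1.0 - share)
        annual[cov] = mean + sd * (year_part + noise)
    return individuals, annual


def _empirical_z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _model_covariate_frame(
    annual: pd.DataFrame, individuals: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Z-scored covariates per record, standardized empirically.

    Generating coefficients are defined per standard deviation of the
    realized covariates — the same scale an analysis of the dataset
    estimates — so the empirical moments, not the configured draw scales,
    define the standardization.  This matters for prey availability, whose
    year-shared component makes realized moments deviate noticeably from
    the configured ones in a short study.
    """
    z = pd.DataFrame(index=annual.index)
    z["experience"] = annual["experience"].astype(float)
    for cov in ANNUAL_COVARIATES:
        z[cov] = _empirical_z(annual[cov].to_numpy(dtype=float))
    spot = individuals.set_index("id")["spot_diameter_mm"]
    spot_z = _empirical_z(spot.to_numpy(dtype=float))
    z["spot"] = pd.Series(spot_z, index=spot.index).loc[annual["id"]].to_numpy()
    z["sex"] = individuals.set_index("id")["sex"].loc[annual["id"]].to_numpy()
    return z


def simulate_reproduction(
    annual: pd.DataFrame,
    individuals: pd.DataFrame,
    true_params: ModelParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the E -> N -> F chain for every individual-year record.

    E ~ Poisson(psi), N ~ Binomial(E, rho_E), F ~ Binomial(N, rho_N), with
    psi, rho_E, rho_N evaluated from the fecundity linear predictors on the
    same covariates; the chain constraint F <= N <= E holds by construction.
    Counts entering downstream predictors are standardized empirically over
    the generated records.
    """
    z = _model_covariate_frame(annual, individuals, config)
    out = annual.copy()
    n_rec = len(annual)
    E = np.zeros(n_rec, dtype=int)
    for sex in ("F", "M"):
        m = (z["sex"] == sex).to_numpy()
        if not m.any():
            continue
        cov = {t: z.loc[m, t].to_numpy() for t in EggModelCoefficients.TERMS[1:]}
        psi = fecundity.egg_rate(true_params.egg[sex], cov)
        psi = psi * np.exp(config.second_brood_logit_shift)
        E[m] = rng.poisson(psi)
    zE = _empirical_z(E.astype(float))

    N = np.zeros(n_rec, dtype=int)
    for sex in ("F", "M"):
        m = (z["sex"] == sex).to_numpy()
        if not m.any():
            continue
        cov = {t: z.loc[m, t].to_numpy() for t in HatchModelCoefficients.TERMS[1:] if t != "eggs"}
        cov["eggs"] = zE[m]
        rho_E = fecundity.hatch_prob(true_params.hatch[sex], cov)
        N[m] = rng.binomial(E[m], rho_E)
    zN = _empirical_z(N.astype(float))

    F = np.zeros(n_rec, dtype=int)
    for sex in ("F", "M"):
        m = (z["sex"] == sex).to_numpy()
        if not m.any():
            continue
        cov = {
            t: z.loc[m, t].to_numpy()
            for t in FledgeModelCoefficients.TERMS[1:]
            if t != "nestlings"
        }
        cov["nestlings"] = zN[m]
        rho_N = fecundity.fledge_prob(true_params.fledge[sex], cov)
        F[m] = rng.binomial(N[m], rho_N)

    out["eggs"] = E
    out["nestlings"] = N
    out["fledglings"] = F
    return out


def simulate_encounters(
    annual: pd.DataFrame,
    individuals: pd.DataFrame,
    true_params: ModelParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate encounter histories from the survival / detection process.

    Returns the encounter table (one code column per occasion) and the
    boolean alive matrix (individual x occasion).  Survival over interval
    t -> t+1 is logit-linear in the year-t covariates and reproduction; a
    bird that dies is recovered (code 2) at the next occasion with the
    group-specific probability r, once, and is never seen again.
    """
    n = len(individuals)
    n_occ = config.n_occasions
    first = individuals["first_occasion"].to_numpy()
    if np.any(first > n_occ - 2):
        raise ConfigurationError("first_occasion must precede the final occasion")

    z = _model_covariate_frame(annual, individuals, config)
    zE = _empirical_z(annual["eggs"].to_numpy(dtype=float))
    zN = _empirical_z(annual["nestlings"].to_numpy(dtype=float))
    zF = _empirical_z(annual["fledglings"].to_numpy(dtype=float))

    # phi per (individual, year) slot.
    phi = np.full((n, n_occ - 1), np.nan)
    rec_id = annual["id"].to_numpy()
    rec_year = annual["occasion"].to_numpy()
    for sex in ("F", "M"):
        m = (z["sex"] == sex).to_numpy()
        if not m.any():
            continue
        cov = {
            t: z.loc[m, t].to_numpy()
            for t in SurvivalCoefficients.TERMS[1:]
            if t not in ("nestlings", "fledglings")
        }
        cov["nestlings"] = zN[m]
        cov["fledglings"] = zF[m]
        phi[rec_id[m], rec_year[m]] = survival_prob(true_params.survival[sex], cov)

    p_ind, r_ind = detection_arrays(true_params.detection, individuals["tag_group"].to_numpy())

    codes = np.zeros((n, n_occ), dtype=int)
    alive = np.zeros((n, n_occ), dtype=bool)
    for i in range(n):
        alive[i, first[i]] = True
    codes[np.arange(n), first] = 1

    for t in range(n_occ - 1):
        at_risk = alive[:, t] & (first <= t)
        if not at_risk.any():
            continue
        u = rng.random(n)
        survives = at_risk & (u < np.where(at_risk, phi[:, t], 0.0))
        dies = at_risk & ~survives
        alive[survives, t + 1] = True
        u_det = rng.random(n)
        recaptured = survives & (u_det < p_ind)
        codes[recaptured, t + 1] = 1
        recovered = dies & (u_det < r_ind)
        codes[recovered, t + 1] = 2

    enc = pd.DataFrame({"id": individuals["id"].to_numpy()})
    for t in range(n_occ):
        enc[f"occ_{t}"] = codes[:, t]
    return enc, alive


def apply_missingness(
    dataset: SimulatedDataset, config: SimulationConfig, rng: np.random.Generator
) -> SimulatedDataset:
    """Mask covariate cells (MCAR) and unobserved reproduction.

    Each covariate cell is masked independently at its configured rate;
    eggs/nestlings/fledglings are masked in every individual-year in which
    the individual was not captured alive (its encounter code is not 1).
    Pre-missingness tables are retained on the returned dataset.
    """
    annual = dataset.annual.copy()
    individuals = dataset.individuals.copy()
    complete_annual = dataset.annual.copy()
    complete_ind = dataset.individuals.copy()

    for cov in ANNUAL_COVARIATES:
        rate = config.missingness_rates.get(cov, 0.0)
        if rate > 0:
            mask = rng.random(len(annual)) < rate
            annual.loc[mask, cov] = np.nan
    spot_rate = config.missingness_rates.get("spot", 0.0)
    if spot_rate > 0:
        mask = rng.random(len(individuals)) < spot_rate
        individuals.loc[mask, "spot_diameter_mm"] = np.nan

    occ_cols = [c for c in dataset.encounters.columns if c.startswith("occ_")]
    codes = dataset.encounters.set_index("id")[occ_cols].to_numpy()
    rec_code = codes[annual["id"].to_numpy(), annual["occasion"].to_numpy()]
    unobserved = rec_code != 1
    for col in ("eggs", "nestlings", "fledglings"):
        annual[col] = annual[col].astype(float)
        annual.loc[unobserved, col] = np.nan

    return SimulatedDataset(
        individuals=individuals,
        annual=annual,
        encounters=dataset.encounters,
        truth=dataset.truth,
        seed=dataset.seed,
        annual_complete=complete_annual,
        individuals_complete=complete_ind,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset: covariates, reproduction, encounters, masks."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    individuals, annual = generate_covariates(config, rng)
    annual = simulate_reproduction(annual, individuals, config.true_params, config, rng)
    encounters, alive = simulate_encounters(annual, individuals, config.true_params, config, rng)

    # Rows only exist for years the bird was alive (a dead owl has no
    # breeding attempt); everything later is latent, not data.
    alive_rec = alive[annual["id"].to_numpy(), annual["occasion"].to_numpy()]
    annual = annual.loc[alive_rec].reset_index(drop=True)

    ds = SimulatedDataset(
        individuals=individuals,
        annual=annual,
        encounters=encounters,
        truth=config.true_params,
        seed=config.seed,
    )
    return apply_missingness(ds, config, rng)


# ---------------------------------------------------------------------------
# On-disk schema


def write_dataset(dataset: SimulatedDataset, path) -> None:
    """Write individuals.csv, annual.csv, encounters.csv and truth.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.individuals.to_csv(path / "individuals.csv", index=False)
    annual = dataset.annual.rename(columns=ANNUAL_CSV_COLUMNS)
    annual.to_csv(path / "annual.csv", index=False)
    dataset.encounters.to_csv(path / "encounters.csv", index=False)
    with open(path / "truth.yaml", "w") as fh:
        yaml.safe_dump({"seed": dataset.seed, "params": dataset.truth.to_dict()}, fh, sort_keys=True)


def read_dataset(path) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    individuals = pd.read_csv(path / "individuals.csv")
    annual = pd.read_csv(path / "annual.csv").rename(
        columns={v: k for k, v in ANNUAL_CSV_COLUMNS.items()}
    )
    encounters = pd.read_csv(path / "encounters.csv")
    with open(path / "truth.yaml") as fh:
        meta = yaml.safe_load(fh)
    return SimulatedDataset(
        individuals=individuals,
        annual=annual,
        encounters=encounters,
        truth=ModelParameters.from_dict(meta["params"]),
        seed=int(meta["seed"]),
    )
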