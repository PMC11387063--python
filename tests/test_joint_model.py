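import numpy as np
import pandas as pd
import pytest

from owlpath import fecundity
from owlpath.covariate_prep import standardize
from owlpath.exceptions import DataError
from owlpath.inference import MCMCConfig, assemble_log_posterior, run_mcmc
from owlpath.joint import JointModel
from owlpath.params import (
    EggModelCoefficients,
    FledgeModelCoefficients,
    HatchModelCoefficients,
    SurvivalCoefficients,
)
from owlpath.survival_mrr import EncounterHistory, history_loglik, survival_prob
from owlpath.synthetic_data import (
    ANNUAL_COVARIATES,
    SimulationConfig,
    apply_missingness,
    default_parameters,
    simulate_dataset,
)
from tests.conftest import no_missingness_rates


def _manual_data_loglik(ds, params):
    """Module-by-module recomputation of the joint data log-likelihood.

    Uses the fecundity and survival module functions directly on the same
    standardization the joint model applies; valid only for fully observed
    datasets with no possible unseen deaths.
    """
    annual = ds.annual
    individuals = ds.individuals.set_index("id")
    z = {}
    for c in ANNUAL_COVARIATES:
        z[c], _, _ = standardize(annual[c].to_numpy(dtype=float))
    spot_z, _, _ = standardize(individuals["spot_diameter_mm"].to_numpy(dtype=float))
    z["spot"] = spot_z[annual["id"].to_numpy()]
    z["experience"] = annual["experience"].to_numpy(dtype=float)
    for name, col in (("eggs", "eggs"), ("nestlings", "nestlings"), ("fledglings", "fledglings")):
        x = annual[col].to_numpy(dtype=float)
        z[name] = (x - x.mean()) / x.std(ddof=1)

    sex_rec = individuals["sex"].loc[annual["id"]].to_numpy()
    E = annual["eggs"].to_numpy(dtype=int)
    N = annual["nestlings"].to_numpy(dtype=int)
    F = annual["fledglings"].to_numpy(dtype=int)

    total = 0.0
    phi_rec = np.empty(len(annual))
    for sex in ("F", "M"):
        m = sex_rec == sex
        cov = lambda cls: {t: np.asarray(z[t])[m] for t in cls.TERMS[1:]}
        psi = fecundity.egg_rate(params.egg[sex], cov(EggModelCoefficients))
        total += fecundity.egg_loglik(E[m], psi).sum()
        rho_e = fecundity.hatch_prob(params.hatch[sex], cov(HatchModelCoefficients))
        total += fecundity.binomial_loglik(N[m], E[m], rho_e).sum()
        rho_n = fecundity.fledge_prob(params.fledge[sex], cov(FledgeModelCoefficients))
        total += fecundity.binomial_loglik(F[m], N[m], rho_n).sum()
        phi_rec[m] = survival_prob(params.survival[sex], cov(SurvivalCoefficients))

    occ_cols = sorted(
        (c for c in ds.encounters.columns if c.startswith("occ_")),
        key=lambda c: int(c.split("_")[1]),
    )
    codes = ds.encounters.set_index("id")[occ_cols]
    n_years = len(occ_cols) - 1
    for ind_id, row in individuals.iterrows():
        first = int(row["first_occasion"])
        h = EncounterHistory(first, tuple(codes.loc[ind_id]))
        sel = annual["id"].to_numpy() == ind_id
        phi = np.full(n_years, 0.5)
        phi[annual.loc[sel, "occasion"].to_numpy()] = phi_rec[sel]
        total += history_loglik(h, phi[first:], params.detection, row["tag_group"])
    return total


def _prior_term(params, prior_scale=1.5):
    return sum(
        -0.5 * float((c.as_array() ** 2).sum()) / prior_scale**2
        for _, _, c in params.submodels()
    )


class TestLogPosteriorContract:
    def test_complete_record_additivity(self, complete_dataset):
        """The joint log posterior is the sum of the module log-likelihoods
        plus the coefficient log-priors."""
        params = default_parameters()
        model = JointModel.from_dataset(complete_dataset)
        lp = assemble_log_posterior(model, params)
        manual = _manual_data_loglik(complete_dataset, params) + _prior_term(params)
        assert lp == pytest.approx(manual, abs=1e-6)

    def test_duplicating_records_doubles_the_data_part(self, complete_dataset):
        params = default_parameters()
        ds = complete_dataset
        n = len(ds.individuals)
        ind2 = ds.individuals.copy()
        ind2["id"] = ind2["id"] + n
        ann2 = ds.annual.copy()
        ann2["id"] = ann2["id"] + n
        enc2 = ds.encounters.copy()
        enc2["id"] = enc2["id"] + n

        class _DS:
            individuals = pd.concat([ds.individuals, ind2], ignore_index=True)
            annual = pd.concat([ds.annual, ann2], ignore_index=True)
            encounters = pd.concat([ds.encounters, enc2], ignore_index=True)

        m1 = JointModel.from_dataset(ds)
        scalers = dict(m1.scalers)
        scalers["eggs"], scalers["nestlings"], scalers["fledglings"] = (
            m1.scale_E, m1.scale_N, m1.scale_F,
        )
        lp1 = m1.log_posterior(params)
        lp2 = JointModel.from_dataset(_DS, scalers=scalers).log_posterior(params)
        data_part = lp1 - _prior_term(params)
        assert lp2 - lp1 == pytest.approx(data_part, rel=1e-9)

    def test_empty_dataset_leaves_log_prior_only(self, complete_dataset):
        params = default_parameters()
        class _Empty:
            individuals = complete_dataset.individuals.iloc[:0]
            annual = complete_dataset.annual.iloc[:0]
            encounters = complete_dataset.encounters.iloc[:0]

        lp = JointModel.from_dataset(_Empty).log_posterior(params)
        assert lp == pytest.approx(_prior_term(params), rel=1e-12)

    def test_missing_data_requires_the_sampler(self, small_dataset):
        model = JointModel.from_dataset(small_dataset)
        with pytest.raises(DataError):
            model.log_posterior(default_parameters())


class TestSamplerStructure:
    def test_no_missingness_means_no_imputation_blocks(self, complete_dataset):
        """With zero missingness the joint model contains no latent
        quantities, so the posterior is exactly the no-imputation model's."""
        model = JointModel.from_dataset(complete_dataset)
        assert model.latent_cols == []
        assert model.mis_repro.size == 0
        assert model.mis_spot.size == 0

    def test_fit_deterministic_given_seed(self, small_dataset):
        cfg = MCMCConfig(n_iterations=300, n_burnin=100, thin=2, seed=21)
        a = run_mcmc(small_dataset, cfg)
        b = run_mcmc(small_dataset, cfg)
        assert np.array_equal(a.chains, b.chains)
        assert a.names == b.names

    def test_recorded_shape_and_names(self, small_dataset):
        cfg = MCMCConfig(n_iterations=200, n_burnin=100, thin=2, seed=1)
        res = run_mcmc(small_dataset, cfg)
        assert res.chains.shape == (4, cfg.n_retained, 66)
        assert res.names[-4:] == ["det.p_ring", "det.p_vhf", "det.r_ring", "det.r_vhf"]
        det = res.chains[:, :, -4:]
        assert np.all((det > 0) & (det < 1))


class TestMissingnessWidensUncertainty:
    def test_cri_width_grows_with_covariate_missingness(self):
        """Masking half the cells of a covariate must widen the posterior
        CrIs of the coefficients that covariate feeds (matched data)."""
        affected = [
            "hatch_F.b_cond_incubation", "hatch_M.b_cond_incubation",
            "survival_F.b_gc_baseline", "survival_M.b_gc_baseline",
        ]
        cfg_fit = MCMCConfig(n_iterations=1000, n_burnin=400, thin=2, n_chains=2, seed=0)
        widths = {0.0: [], 0.5: []}
        for rep in range(20):
            base = SimulationConfig(
                n_individuals=100,
                n_occasions=4,
                missingness_rates=no_missingness_rates(),
                seed=500 + rep,
            )
            ds0 = simulate_dataset(base)
            heavy = SimulationConfig(
                n_individuals=100,
                n_occasions=4,
                missingness_rates=dict(
                    no_missingness_rates(), cond_incubation=0.5, gc_baseline=0.5
                ),
                seed=500 + rep,
            )
            ds1 = apply_missingness(ds0, heavy, np.random.default_rng(900 + rep))
            for rate, ds in ((0.0, ds0), (0.5, ds1)):
                cfg = MCMCConfig(**{**cfg_fit.__dict__, "seed": 1000 + rep})
                summ = run_mcmc(ds, cfg).summary()
                w = (summ.loc[affected, "cri_high"] - summ.loc[affected, "cri_low"]).mean()
                widths[rate].append(w)
        assert np.mean(widths[0.5]) > np.mean(widths[0.0])
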