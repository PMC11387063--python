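import numpy as np
import pandas as pd
import pytest

from owlpath.exceptions import ConfigurationError
from owlpath.params import DetectionParameters
from owlpath.synthetic_data import (
    ANNUAL_COVARIATES,
    SimulationConfig,
    apply_missingness,
    default_parameters,
    generate_covariates,
    read_dataset,
    simulate_dataset,
    simulate_encounters,
    simulate_reproduction,
    write_dataset,
)
from tests.conftest import no_missingness_rates


def _cfg(**kwargs):
    kwargs.setdefault("n_individuals", 100)
    kwargs.setdefault("seed", 3)
    return SimulationConfig(**kwargs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_individuals", 0),
            ("n_occasions", 1),
            ("sex_ratio", 1.2),
            ("prop_tagged", -0.1),
        ],
    )
    def test_invalid_field_is_named_in_error(self, field, value):
        cfg = _cfg(**{field: value})
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            cfg.validate()

    def test_bad_missingness_rate(self):
        cfg = _cfg(missingness_rates=dict(no_missingness_rates(), gc_baseline=1.5))
        with pytest.raises(ConfigurationError, match="gc_baseline"):
            cfg.validate()


class TestCovariateGeneration:
    def test_no_missingness_before_masking(self):
        cfg = _cfg()
        individuals, annual = generate_covariates(cfg, np.random.default_rng(0))
        assert not annual[list(ANNUAL_COVARIATES)].isna().any().any()

    def test_spot_is_an_individual_trait(self):
        cfg = _cfg()
        individuals, _ = generate_covariates(cfg, np.random.default_rng(0))
        assert individuals["spot_diameter_mm"].notna().all()
        assert individuals["id"].is_unique

    def test_experience_codes_zero_then_one(self):
        cfg = _cfg(n_individuals=200)
        individuals, annual = generate_covariates(cfg, np.random.default_rng(0))
        first = individuals.set_index("id")["first_occasion"]
        expected = (annual["occasion"] > first.loc[annual["id"]].to_numpy()).astype(int)
        assert (annual["experience"].to_numpy() == expected.to_numpy()).all()

    def test_laying_date_mean_matches_configuration(self):
        cfg = _cfg(n_individuals=6000)
        _, annual = generate_covariates(cfg, np.random.default_rng(5))
        assert len(annual) > 10_000
        assert annual["laying_date"].mean() == pytest.approx(100.0, abs=0.5)


class TestReproductionChain:
    def test_chain_constraint_holds_everywhere(self, small_dataset):
        complete = small_dataset.annual_complete
        assert (complete["fledglings"] <= complete["nestlings"]).all()
        assert (complete["nestlings"] <= complete["eggs"]).all()

    def test_mean_eggs_matches_poisson_rate(self):
        params = default_parameters()
        for sex in ("F", "M"):
            c = params.egg[sex]
            c.b_experience = c.b_laying_date = 0.0
            c.b_prey_sm_prelay = c.b_prey_vole_prelay = 0.0
            c.intercept = float(np.log(6.0))
        cfg = _cfg(n_individuals=12_000, true_params=params)
        rng = np.random.default_rng(9)
        individuals, annual = generate_covariates(cfg, rng)
        annual = simulate_reproduction(annual, individuals, params, cfg, rng)
        assert len(annual) >= 25_000
        assert annual["eggs"].mean() == pytest.approx(6.0, abs=0.1)

    def test_certain_success_collapses_chain(self):
        params = default_parameters()
        for sex in ("F", "M"):
            params.hatch[sex] = type(params.hatch[sex])(intercept=50.0)
            params.fledge[sex] = type(params.fledge[sex])(intercept=50.0)
        cfg = _cfg(true_params=params)
        rng = np.random.default_rng(1)
        individuals, annual = generate_covariates(cfg, rng)
        annual = simulate_reproduction(annual, individuals, params, cfg, rng)
        assert (annual["fledglings"] == annual["eggs"]).all()

    def test_certain_fledging_failure(self):
        params = default_parameters()
        for sex in ("F", "M"):
            params.fledge[sex] = type(params.fledge[sex])(intercept=-50.0)
        cfg = _cfg(true_params=params)
        rng = np.random.default_rng(1)
        individuals, annual = generate_covariates(cfg, rng)
        annual = simulate_reproduction(annual, individuals, params, cfg, rng)
        assert (annual["fledglings"] == 0).all()


class TestEncounterProcess:
    def _simulate(self, params, n=300, n_occ=4, seed=2):
        cfg = _cfg(n_individuals=n, n_occasions=n_occ, true_params=params, seed=seed)
        rng = np.random.default_rng(seed)
        individuals, annual = generate_covariates(cfg, rng)
        annual = simulate_reproduction(annual, individuals, params, cfg, rng)
        enc, alive = simulate_encounters(annual, individuals, params, cfg, rng)
        occ_cols = [f"occ_{t}" for t in range(n_occ)]
        return individuals, enc[occ_cols].to_numpy(), alive

    def test_certain_survival_and_detection(self):
        params = default_parameters()
        for sex in ("F", "M"):
            params.survival[sex] = type(params.survival[sex])(intercept=60.0)
        params.detection = DetectionParameters(
            p_ring=1 - 1e-12, p_vhf=1 - 1e-12, r_ring=0.5, r_vhf=0.5
        )
        individuals, codes, _ = self._simulate(params)
        first = individuals["first_occasion"].to_numpy()
        for i in range(len(individuals)):
            assert (codes[i, first[i]:] == 1).all()

    def test_immediate_death_certain_recovery(self):
        params = default_parameters()
        for sex in ("F", "M"):
            params.survival[sex] = type(params.survival[sex])(intercept=-60.0)
        params.detection = DetectionParameters(
            p_ring=0.5, p_vhf=0.5, r_ring=1 - 1e-12, r_vhf=1 - 1e-12
        )
        individuals, codes, _ = self._simulate(params)
        first = individuals["first_occasion"].to_numpy()
        for i in range(len(individuals)):
            assert codes[i, first[i]] == 1
            assert codes[i, first[i] + 1] == 2
            assert (codes[i, first[i] + 2 :] == 0).all()

    def test_two_occasion_survive_and_recapture_rate(self):
        """P(code 1 at the second occasion) = phi * p = 0.6 * 0.5."""
        params = default_parameters()
        for sex in ("F", "M"):
            params.survival[sex] = type(params.survival[sex])(
                intercept=float(np.log(0.6 / 0.4))
            )
        params.detection = DetectionParameters(p_ring=0.5, p_vhf=0.5, r_ring=0.3, r_vhf=0.3)
        _, codes, _ = self._simulate(params, n=100_000, n_occ=2, seed=5)
        frac = (codes[:, 1] == 1).mean()
        assert frac == pytest.approx(0.30, abs=0.01)

    def test_history_legality(self, small_dataset):
        occ_cols = [c for c in small_dataset.encounters.columns if c.startswith("occ_")]
        codes = small_dataset.encounters[occ_cols].to_numpy()
        first = small_dataset.individuals["first_occasion"].to_numpy()
        for i in range(codes.shape[0]):
            assert codes[i, first[i]] == 1
            assert (codes[i, : first[i]] == 0).all()
            dead = np.flatnonzero(codes[i] == 2)
            assert dead.size <= 1
            if dead.size:
                assert (codes[i, dead[0] + 1 :] == 0).all()


class TestMissingness:
    def test_zero_rates_leave_covariates_complete(self, complete_dataset):
        assert not complete_dataset.annual[list(ANNUAL_COVARIATES)].isna().any().any()
        assert not complete_dataset.annual[["eggs", "nestlings", "fledglings"]].isna().any().any()

    def test_rate_one_masks_every_cell(self):
        rates = dict(no_missingness_rates(), gc_baseline=1.0)
        ds = simulate_dataset(_cfg(missingness_rates=rates))
        assert ds.annual["gc_baseline"].isna().all()

    def test_empirical_rate_matches_configured_rate(self):
        rates = dict(no_missingness_rates(), laying_date=0.3)
        params = default_parameters()
        for sex in ("F", "M"):
            params.survival[sex] = type(params.survival[sex])(intercept=60.0)
        params.detection = DetectionParameters(
            p_ring=1 - 1e-12, p_vhf=1 - 1e-12, r_ring=0.5, r_vhf=0.5
        )
        ds = simulate_dataset(
            _cfg(n_individuals=4000, missingness_rates=rates, true_params=params)
        )
        assert len(ds.annual) > 10_000
        assert ds.annual["laying_date"].isna().mean() == pytest.approx(0.3, abs=0.02)

    def test_reproduction_missing_exactly_when_not_captured(self, small_dataset):
        occ_cols = [c for c in small_dataset.encounters.columns if c.startswith("occ_")]
        codes = small_dataset.encounters.set_index("id")[occ_cols].to_numpy()
        rec_code = codes[small_dataset.annual["id"], small_dataset.annual["occasion"]]
        missing = small_dataset.annual["eggs"].isna().to_numpy()
        assert (missing == (rec_code != 1)).all()

    def test_truth_is_retained(self, small_dataset):
        assert small_dataset.annual_complete is not None
        assert not small_dataset.annual_complete["eggs"].isna().any()


class TestIndividualRecords:
    def test_records_are_validated_views(self, small_dataset):
        recs = list(small_dataset.individual_records())
        assert len(recs) == len(small_dataset.individuals)
        r = recs[0]
        assert r.encounter.codes[r.first_occasion] == 1
        assert set(r.annual["id"]) <= {r.id}


class TestDeterminismAndRoundTrip:
    def test_identical_seeds_give_identical_datasets(self):
        a = simulate_dataset(_cfg(seed=9))
        b = simulate_dataset(_cfg(seed=9))
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        pd.testing.assert_frame_equal(a.annual, b.annual)
        pd.testing.assert_frame_equal(a.encounters, b.encounters)

    def test_write_read_round_trip(self, tmp_path, small_dataset):
        write_dataset(small_dataset, tmp_path)
        back = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(small_dataset.individuals, back.individuals)
        pd.testing.assert_frame_equal(small_dataset.annual, back.annual)
        pd.testing.assert_frame_equal(small_dataset.encounters, back.encounters)
        assert back.truth.to_dict() == small_dataset.truth.to_dict()
        assert back.seed == small_dataset.seed

    def test_files_byte_identical_across_runs(self, tmp_path):
        for sub in ("a", "b"):
            write_dataset(simulate_dataset(_cfg(seed=4)), tmp_path / sub)
        for name in ("individuals.csv", "annual.csv", "encounters.csv", "truth.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_empty_individual_list_writes_headers(self, tmp_path):
        ds = simulate_dataset(_cfg(n_individuals=1, seed=0))
        ds.individuals = ds.individuals.iloc[:0]
        ds.annual = ds.annual.iloc[:0]
        ds.encounters = ds.encounters.iloc[:0]
        write_dataset(ds, tmp_path)
        back = read_dataset(tmp_path)
        assert len(back.individuals) == 0
        assert list(back.encounters.columns) == list(ds.encounters.columns)
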