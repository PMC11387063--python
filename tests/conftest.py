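import numpy as np
import pandas as pd
import pytest

from owlpath.params import DetectionParameters
from owlpath.synthetic_data import (
    DEFAULT_MISSINGNESS_RATES,
    SimulationConfig,
    default_parameters,
    simulate_dataset,
)


def no_missingness_rates():
    return {c: 0.0 for c in DEFAULT_MISSINGNESS_RATES}


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-owl study with the default (paper-like) missingness."""
    return simulate_dataset(SimulationConfig(n_individuals=120, seed=7))


@pytest.fixture(scope="session")
def complete_dataset():
    """A fully observed study: certain detection, near-certain survival.

    Every bird is captured at every occasion and no covariate is masked, so
    the dataset carries no latent quantities at all.
    """
    params = default_parameters()
    for sex in ("F", "M"):
        params.survival[sex].intercept = 50.0  # phi ~ 1: nobody dies
    params.detection = DetectionParameters(
        p_ring=1.0 - 1e-12, p_vhf=1.0 - 1e-12, r_ring=0.5, r_vhf=0.5
    )
    cfg = SimulationConfig(
        n_individuals=60,
        n_occasions=4,
        true_params=params,
        missingness_rates=no_missingness_rates(),
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
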