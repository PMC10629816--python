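import numpy as np
import pytest

from snaburst.simulate import EmbryoConfig, KineticField, default_field, generate_embryo
from snaburst.thermo import EnhancerOccupancyModel


@pytest.fixture(scope="session")
def fitted_model() -> EnhancerOccupancyModel:
    """Default occupancy model fitted once and shared (deterministic)."""
    return EnhancerOccupancyModel().fit()


@pytest.fixture(scope="session")
def small_embryo():
    """50 wildtype nuclei, 30 min movie, default kinetics."""
    cfg = EmbryoConfig(n_nuclei=50, duration=30.0, genotype="WT", seed=11)
    return generate_embryo(cfg, default_field())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def noiseless_field() -> KineticField:
    return KineticField(kon=0.5, koff=0.25, loading_rate=200.0, noise_sd=0.0)
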