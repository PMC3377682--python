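import numpy as np
import pytest

from carotscan import synthetic
from carotscan.divsim import BundleTemplate
from carotscan.types import DivergenceModelParams, SimConfig


@pytest.fixture(scope="session")
def scenario():
    return synthetic.SyntheticScenario(
        seed=1234, regimes={"PDS": "sweep", "CRTISO": "balancing"})


@pytest.fixture(scope="session")
def bundle(scenario):
    b, _truths = synthetic.generate_study_bundle(scenario)
    return b


@pytest.fixture(scope="session")
def control_bundle(scenario):
    return synthetic.generate_control_loci(scenario)


@pytest.fixture(scope="session")
def template():
    return BundleTemplate(
        n_west=23, n_east=23,
        seq_lengths=(("B1D", 550), ("JW3D", 600), ("SB4A", 650)),
        ssr_meta=tuple((f"SSR{k:02d}", 2, (8, 30)) for k in range(1, 18)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def single_pop_params():
    """T_d = 0 with equal sizes collapses to one panmictic population."""
    return DivergenceModelParams(N_W=1000, N_E=1000, N_A=1000, T_d=0.0, mu_seq=2.5e-6)


@pytest.fixture(scope="session")
def seq_config():
    return SimConfig(n_west=23, n_east=23, length=1000)
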