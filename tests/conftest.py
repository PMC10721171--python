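import numpy as np
import pytest

from pestevol import FarmSimulation, GMatrixMiner, Network, SimConfig

#: The worked-example network: 3 loci, 2 traits, 2 layer maps.
EXAMPLE_LOCI = np.array([0.1, -0.1, 0.2])
EXAMPLE_A = np.array([[0.4, 0.1], [-1.2, -0.6], [0.2, 2.2]])
EXAMPLE_B = np.array([[1.3, -0.5], [-0.1, 0.0]])
EXAMPLE_C = np.array([[2.2, 0.9], [1.6, 0.8]])
EXAMPLE_TRAITS = np.array([0.2998, 0.1081])

#: Published target / achieved covariance pair for the stress arithmetic.
TARGET_GMATRIX = np.array([[1.0, -0.4], [-0.4, 1.0]])
ACHIEVED_COV = np.array([[1.0008181, -0.3925799], [-0.3925799, 1.0271340]])
ACHIEVED_MSD = 2.1176024e-4


@pytest.fixture
def example_network() -> Network:
    return Network(EXAMPLE_A, [EXAMPLE_B, EXAMPLE_C])


@pytest.fixture
def identity_network() -> Network:
    """2-locus, 2-trait network whose traits equal its loci exactly."""
    return Network(np.eye(2), [np.eye(2)])


@pytest.fixture(scope="session")
def mined_network_result():
    """One converged mining run shared by the simulation tests."""
    miner = GMatrixMiner(TARGET_GMATRIX, loci=3, layers=2, term_cri=-6.0, max_gen=1000)
    result = miner.fit(seed=20240901)
    assert result.converged
    return result


def make_state(cfg: SimConfig, network: Network, seed: int = 0):
    """Build a ready-to-step simulation state for ecology tests."""
    sim = FarmSimulation(cfg, network)
    return sim._build_state(np.random.default_rng(seed))
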