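import numpy as np
import pytest

from ratequity import SubgroupEstimates, from_summaries
from ratequity.fixtures import mto_summary_rows
from ratequity.simulation import EffectDistributionSpec, SimulationConfig, simulate_trial


@pytest.fixture
def mto_estimates() -> SubgroupEstimates:
    """Summary-level subgroup estimates from the MTO psychological-distress analysis."""
    return from_summaries(mto_summary_rows())


@pytest.fixture
def three_group_config() -> SimulationConfig:
    return SimulationConfig(effect_spec=EffectDistributionSpec(), seed=7)


@pytest.fixture
def small_trial(three_group_config):
    """One seeded trial with known subgroup effects."""
    effects = np.array([0.5, -0.5, 1.0])
    return simulate_trial(three_group_config, effects, seed=11), effects


def random_estimates(rng, G: int, diagonal: bool = True,
                     se_scale: float = 0.3) -> SubgroupEstimates:
    """Random valid SubgroupEstimates for property-style tests."""
    tau = rng.normal(size=G)
    se = se_scale * (0.2 + rng.random(G))
    if diagonal:
        cov = np.diag(se**2)
    else:
        A = rng.normal(size=(G, G)) * se_scale / np.sqrt(G)
        cov = A @ A.T + np.diag(se**2)
    p = rng.dirichlet(np.ones(G))
    return SubgroupEstimates(labels=[f"g{i}" for i in range(G)], tau_hat=tau,
                             cov=cov, p=p)
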