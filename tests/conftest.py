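import numpy as np
import pytest

from excipol.copolymer_sim import (
    ChainLengthModel,
    MonomerSpec,
    ReactivityRatios,
    SimConfig,
)
from excipol.synthetic import make_table4_fixture


@pytest.fixture(scope="session")
def table4_records():
    return make_table4_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_moni_config(
    mean_dp: float,
    dispersity: float,
    n_chains: int = 20_000,
    seed: int = 0,
    feed=(0.77, 0.23),
    ratios=ReactivityRatios(),
    pool_mode: str = "infinite_feed",
    family: str = "schulz_zimm",
) -> SimConfig:
    """Standard two-monomer simulation config used across the suite."""
    return SimConfig(
        monomers=(
            MonomerSpec("Morph", 141.17, feed[0]),
            MonomerSpec("Nipam", 113.16, feed[1]),
        ),
        ratios=ratios,
        length_model=ChainLengthModel(mean_dp, dispersity, family=family),
        n_chains=n_chains,
        pool_mode=pool_mode,
        seed=seed,
    )


@pytest.fixture
def moni_config_factory():
    return make_moni_config
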