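from __future__ import annotations

import numpy as np
import pytest

from nailseq import GenomeLayout, SimConfig, generate_truth


@pytest.fixture(scope="session")
def small_genome() -> GenomeLayout:
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def truth(sim_config):
    return generate_truth(sim_config, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
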