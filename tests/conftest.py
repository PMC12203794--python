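import numpy as np
import pandas as pd
import pytest

from episilence import (
    PipelineConfig,
    SimulationConfig,
    simulate_cohort,
    split_by_driver,
)


@pytest.fixture(scope="session")
def small_sim():
    """One mid-size omics cohort with planted effects, shared across tests."""
    cfg = SimulationConfig(n_samples=200, n_genes=120, n_target_genes=5,
                           rng_seed=42)
    bundle, truth = simulate_cohort(cfg, 0)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_groups(small_sim):
    _, bundle, _ = small_sim
    return split_by_driver(bundle.expression, "DNMT3B")


@pytest.fixture()
def default_config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
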