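import numpy as np
import pytest

from amniograph import syndata
from amniograph.pipeline import PipelineConfig, derive_seed, run_pipeline


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulated atlas shared across expensive tests."""
    cfg = syndata.build_default_config()
    m, truth = syndata.simulate_dataset(cfg, seed=11)
    return cfg, m, truth


@pytest.fixture(scope="session")
def small_sim():
    """Reduced atlas for fast unit tests (structure preserved)."""
    cfg = syndata.build_default_config(
        {
            "n_genes": 500,
            "n_cells_per_condition": 300,
            "marker_block_size": 10,
            "regulon_n_targets": 20,
            "n_naive_genes": 10,
            "n_primed_genes": 10,
        }
    )
    m, truth = syndata.simulate_dataset(cfg, seed=5)
    return cfg, m, truth


@pytest.fixture(scope="session")
def pipeline_run():
    """One full default pipeline run plus the matching ground truth."""
    config = PipelineConfig(seed=7)
    report = run_pipeline(config)
    sim_cfg = syndata.build_default_config(config.sim_overrides)
    _, truth = syndata.simulate_dataset(sim_cfg, seed=derive_seed(config.seed, "simulate"))
    return config, report, truth
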