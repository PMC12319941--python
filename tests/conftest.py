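import numpy as np
import pytest

from navscene import PipelineConfig, SimulationConfig, demo_effects, simulate_betas


@pytest.fixture(scope="session")
def null_config():
    """Default (all-zero-effect) configuration at full study scale."""
    return SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def demo_config():
    """All injected components at 1 within-run noise SD, 8 subjects."""
    return SimulationConfig(seed=202, n_subjects=8, **demo_effects())


@pytest.fixture(scope="session")
def demo_experiment(demo_config):
    return simulate_betas(demo_config, rois=("OPA",))


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One fast end-to-end pipeline run shared by orchestration tests."""
    from navscene import run_pipeline

    cfg = PipelineConfig(
        simulation=SimulationConfig(seed=303, n_subjects=5, **demo_effects()),
        rois=("OPA", "PPA", "MPA"),
        n_mask_voxels=60,
        n_roi_voxels=30,
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
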