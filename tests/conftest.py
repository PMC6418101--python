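import numpy as np
import pytest

import fibroscreen as fs


@pytest.fixture(scope="session")
def small_screen():
    """Two-donor screen with a small shRNA panel, moderate noise."""
    cfg = fs.ScreenConfig(
        n_donors=2, wells_per_condition=24, fold_separation=3.0,
        cv_noise=0.10, shrna_panel=fs.uniform_panel(5, 3), seed=11,
    )
    plate_map, well_table, truth = fs.simulate_screen(cfg)
    return cfg, plate_map, well_table, truth


@pytest.fixture(scope="session")
def oracle_study():
    """The small two-batch study frozen against the external references."""
    cfg = fs.StudyConfig(
        n_probes=300, n_signature=30, n_ssc=5, n_healthy=5,
        n_replicates=3, seed=123,
    )
    matrix, meta, truth = fs.simulate_expression_study(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture
def noise_free_spec():
    return fs.ImageSpec(poisson_noise=False, read_noise_sd=0.0)
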