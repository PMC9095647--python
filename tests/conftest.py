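import numpy as np
import pytest

from cyclicproc.synthetic_fixtures import (SimImageConfig, SimTableConfig,
                                           simulate_cell_table,
                                           simulate_image_experiment)


@pytest.fixture(scope="session")
def small_scene():
    """A clean single-round 512x512 scene with 200 non-touching nuclei."""
    cfg = SimImageConfig(shape=(512, 512), n_cells=200, seed=2,
                         max_shift_px=0, max_rotation_deg=0,
                         rounds=(1,), blank_rounds=(), channels=("c2",))
    return simulate_image_experiment(cfg)


@pytest.fixture(scope="session")
def jittered_scene():
    """A 3-round scene with per-round registration jitter."""
    cfg = SimImageConfig(shape=(256, 256), n_cells=60, seed=1,
                         max_shift_px=6, max_rotation_deg=1.5)
    return simulate_image_experiment(cfg)


@pytest.fixture(scope="session")
def cell_table():
    """3 cores x 3 batches x 1000 cells with planted exclusivity and batch
    effects."""
    cfg = SimTableConfig(seed=3)
    table, truth = simulate_cell_table(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
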