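import numpy as np
import pytest

import granupls as g


@pytest.fixture(scope="session")
def coarse_grid():
    """Reduced-resolution instrument grid (8x the native step) for speed."""
    return g.WavenumberGrid(start=10000.0, stop=4000.0, step=15.424)


@pytest.fixture(scope="session")
def small_cfg(coarse_grid):
    return g.SimulationConfig(grid=coarse_grid, n_samples=12, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """12 samples x 4 mesh classes x 3 replicates on the coarse grid."""
    return g.generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
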