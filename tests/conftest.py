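import numpy as np
import pytest

from protraj.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort on an 8^3 grid for IO/pipeline tests."""
    cfg = SimulationConfig(n_subjects=80, grid_shape=(8, 8, 8),
                           region_center=(4, 4, 4), region_radius=2.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 300 subjects, ~10^4 voxels."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_rfe(default_cohort):
    """PLS-RFE fitted on the default cohort's density -> memory regression."""
    from protraj.pls_rfe import PLSRFE

    c = default_cohort
    return PLSRFE(c.voxels, c.table.adni_mem.to_numpy()).fit(seed=1)


@pytest.fixture(scope="session")
def separable_classes():
    """Two well-separated Gaussian classes (6 SD apart), 100 per class."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0.0, 1.0, (100, 3)), rng.normal(6.0, 1.0, (100, 3))])
    y = np.array(["stable"] * 100 + ["progressive"] * 100)
    return X, y
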