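import numpy as np
import pytest

from jackfc import SyntheticSpec, make_cohort, simulate_subject


@pytest.fixture(scope="session")
def null_series():
    """One subject of pure independent noise (no planted edges)."""
    spec = SyntheticSpec(n_rois=6, n_timepoints=100, master_seed=11)
    return simulate_subject(spec, 0)


@pytest.fixture(scope="session")
def planted_series():
    """One subject with a strong planted edge (0, 1) at r = 0.8."""
    spec = SyntheticSpec(
        n_rois=6, n_timepoints=294, planted_edges=[(0, 1, 0.8)], master_seed=11
    )
    return simulate_subject(spec, 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, 8 ROIs, two planted edges at r = 0.7, T = 60."""
    spec = SyntheticSpec(
        n_rois=8,
        n_timepoints=60,
        planted_edges=[(0, 1, 0.7), (2, 3, 0.7)],
        master_seed=21,
        n_subjects=6,
    )
    return make_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
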