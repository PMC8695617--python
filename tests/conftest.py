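import numpy as np
import pytest

from connparc.phantom import simulate_cohort, small_null_config
from connparc.volio import BinaryMask, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def highsnr_dataset():
    """Small signal-dominated phantom (coupling 10x noise), reused read-only."""
    cfg = small_null_config(
        master_seed=42,
        coupling_amplitude=10.0,
        n_subjects=4,
        n_timepoints=150,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def full_mask():
    def _make(shape):
        return BinaryMask(VolumeGrid(shape), np.ones(shape, dtype=bool))

    return _make
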