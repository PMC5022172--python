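import dataclasses

import numpy as np
import pytest

from cfcausal import DEFAULT_MONTAGE, SynthConfig

#: compact montage used by the scaled simulation tests: 5 frontal sensors and
#: 5 parieto-occipital sensors including three right-hemisphere PO channels
SMALL_LABELS = ("FZ", "F3", "F4", "FC1", "FC2", "PZ", "PO7", "P6", "PO8", "O2")


@pytest.fixture(scope="session")
def small_montage():
    return DEFAULT_MONTAGE.subset(SMALL_LABELS)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config(small_montage):
    """Scaled-down study conditions for simulation-backed tests."""
    return SynthConfig(
        montage=small_montage,
        n_trials_correct=(10,) * 5,
        n_trials_wrong=(10,) * 5,
        duration_base_ms=4200.0,
        duration_step_ms=100.0,
        duration_jitter_ms=250.0,
        seed=0,
    )


def replace(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
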