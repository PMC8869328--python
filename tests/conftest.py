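import numpy as np
import pytest

from epenet.montage import MONTAGE_30
from epenet.preprocess import DEFAULT_BANDS
from epenet.synthgen import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """A very small cohort: 2 subjects per group, 4 channels, 6 s at 64 Hz."""
    labels = tuple(MONTAGE_30[i] for i in (0, 9, 19, 29))
    return CohortConfig(
        group_sizes={"SCI": 2, "MCI": 2, "AD": 2},
        n_channels=4,
        channel_labels=labels,
        fs=64.0,
        segment_seconds=6.0,
        bands={k: DEFAULT_BANDS[k] for k in ("delta", "alpha")},
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
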