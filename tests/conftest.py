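import numpy as np
import pytest

from corticlass.synthetic import (
    LeadField,
    SyntheticConfig,
    block_roi_assignment,
    make_lead_field,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects_dp=2, n_subjects_hc=3, n_channels=8, n_sources=16,
        n_rois=4, sampling_rate=250.0, duration=8.0, noise_sd=0.1,
        class_effect=3.0, domain_shift_sd=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def small_lead_field(small_config) -> LeadField:
    return make_lead_field(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_lead_field):
    return simulate_dataset(small_config, small_lead_field)


@pytest.fixture
def random_lead_field() -> LeadField:
    rng = np.random.default_rng(11)
    return LeadField(
        gain=rng.standard_normal((4, 8)),
        roi_of_source=block_roi_assignment(8, 4),
        source_orientation=np.tile([0.0, 0.0, 1.0], (8, 1)),
    )
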