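import numpy as np
import pytest

from szevents.simulate import SeizureSignature, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Four small subjects with a strong seizure signature (session-shared)."""
    cfg = SimConfig(
        n_subjects=4,
        records_per_subject=2,
        record_duration_s=150.0,
        seizures_per_subject=(1, 2),
        seizure_duration_s=(20.0, 40.0),
        signature=SeizureSignature(gain=4.0),
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
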