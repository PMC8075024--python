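import numpy as np
import pytest

from dualecg.syndata import NO_NOISE, NoiseSpec, generate_record


@pytest.fixture(scope="session")
def clean_n_record():
    """10 s all-normal record, no noise, no RR jitter."""
    return generate_record(10.0, class_probs=(1, 0, 0, 0), mean_rr=0.8,
                           rr_jitter=0.0, noise=NO_NOISE, seed=7,
                           record_id="cleanN")


@pytest.fixture(scope="session")
def mixed_record():
    """60 s record with all four classes and realistic artifact noise."""
    noise = NoiseSpec(baseline_amp=0.15, pli_amp=0.05, white_sigma=0.03, seed=11)
    return generate_record(60.0, class_probs=(0.7, 0.1, 0.1, 0.1), mean_rr=0.8,
                           rr_jitter=0.05, noise=noise, seed=3,
                           record_id="mixed")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
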