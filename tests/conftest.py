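import numpy as np
import pytest

from feaclusmoo import SyntheticSpec, generate_mixture


@pytest.fixture(scope="session")
def spherical_dataset():
    """300 samples, 3 well-separated spherical clusters in 2 relevant
    dimensions plus 3 uniform noise dimensions, 10% labeled."""
    spec = SyntheticSpec(
        n=300, k_true=3, relevant_d=2, noise_d=3, shapes="spherical",
        separation=6.0, labeled_fraction=0.1, seed=11,
    )
    dataset, relevant_mask = generate_mixture(spec)
    return dataset, relevant_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
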