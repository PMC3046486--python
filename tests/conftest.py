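import numpy as np
import pytest

from chromalign import RegionMatrix, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_random_matrix(rng):
    """6 random regions of 18 bins (S = 10 with an 8-bin frame)."""
    return RegionMatrix.from_values(rng.normal(size=(6, 18)), bin_size=10)


@pytest.fixture
def planted_matrix():
    """Noise-free planted-shift dataset with its truth."""
    return generate_dataset(
        "tss_like", n=10, length_bins=80, max_shift_bins=8,
        noise_sd=0.0, master_seed=42,
    )
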