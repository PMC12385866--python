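import numpy as np
import pytest

from axonpolar import SyntheticConfig, generate_labels, generate_lengths


@pytest.fixture(scope="session")
def single_truth():
    """Published single-neurite sigmoid parameters (Lc, sigma) in μm."""
    return 43.3, 13.7


@pytest.fixture()
def small_dataset(single_truth):
    """One seeded (lengths, labels) draw at the single-neurite truth, n=200."""
    Lc, sigma = single_truth
    cfg = SyntheticConfig(n=200, seed=42)
    lengths = generate_lengths(cfg)
    labels = generate_labels(lengths, Lc, sigma, seed=42)
    return lengths, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
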