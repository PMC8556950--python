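"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest

from ramanstage import preprocess, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """30 spectra/class at default noise, with ground truth."""
    cfg = synthetic.SyntheticConfig(n_per_class=30, seed=11)
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_clean(small_dataset):
    """Preprocessed version of the small dataset plus per-spectrum QC."""
    spectra_set, _ = small_dataset
    clean, details = preprocess.preprocess_set(spectra_set, return_details=True)
    return clean, details


@pytest.fixture(scope="session")
def separable_matrix():
    """Tiny linearly separable 3-class problem (class means 10 sigma apart)."""
    rng = np.random.default_rng(7)
    n, p = 30, 12
    means = np.zeros((3, p))
    means[0, 0] = 10.0
    means[1, 1] = 10.0
    means[2, 2] = 10.0
    X = np.vstack([rng.normal(means[k], 1.0, size=(n, p)) for k in range(3)])
    y = np.repeat(["a", "b", "c"], n)
    return X, y
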