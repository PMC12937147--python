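"""Shared fixtures: small phantom datasets generated once per session."""

import numpy as np
import pytest

import mammofusion as mf


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless phantom spec at moderate resolution for mask-oracle checks."""
    return mf.PhantomSpec(noise_sd=0.0, seed=42, image_size=256)


@pytest.fixture(scope="session")
def clean_case(clean_spec):
    """One noiseless malignant case (CC, MLO) with ground-truth masks."""
    rng = np.random.default_rng(7)
    return mf.generate_case(clean_spec, "malignant", rng, laterality="L")


@pytest.fixture(scope="session")
def small_dataset():
    """16 cases (8 benign + 8 malignant) at 128 px with mild noise."""
    spec = mf.PhantomSpec(seed=5, image_size=128)
    records, manifest = mf.generate_dataset(spec, 8, 8)
    return records, manifest


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    """The 16-case dataset preprocessed to 32x32 pairs (fast model input)."""
    records, _ = small_dataset
    samples, _ = mf.preprocess_records(records, mf.PreprocessConfig(target_size=32))
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
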