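import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import afvec

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_dataset():
    """A small drifted metapopulation: 5 pops × 8 samples, 2 chroms × 300 SNPs."""
    design = afvec.SyntheticDesign(n_chroms=2, snps_per_chrom=300, samples_per_pop=8)
    return afvec.generate(design, seed=42)


@pytest.fixture
def small_freqs(small_dataset):
    return afvec.compute_frequencies(small_dataset.variants, small_dataset.registry)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_unit_rows(rng, m=4, n=200):
    """Random row-normalized ΔAF-like matrix."""
    X = rng.uniform(-1, 1, size=(m, n))
    return X / np.linalg.norm(X, axis=1, keepdims=True)
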