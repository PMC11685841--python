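import numpy as np
import pytest

import thermocomb as tc


@pytest.fixture(scope="session")
def toy_wild_type():
    """Short parent sequence used by variant-algebra tests."""
    return "MKLDVFITREAQGHWCYNSP"


@pytest.fixture(scope="session")
def additive_landscape_10():
    """10-site purely additive landscape with known coefficients, zero noise."""
    coeffs = tuple(np.round(np.random.default_rng(0).uniform(-2.0, 2.0, 10), 3))
    spec = tc.LandscapeSpec(
        n_sites=10, wt_tm=59.53, additive=coeffs,
        noise_sd=0.0, activity_noise_sd=0.0,
    )
    return tc.generate_landscape(spec)


@pytest.fixture(scope="session")
def creatinase_landscape_12():
    """The 12-site study-like landscape (planted sign site + synergy pair)."""
    return tc.generate_landscape(tc.creatinase_like_spec(n_sites=12))


@pytest.fixture(scope="session")
def fast_head_config():
    """Desk-scale training settings for one-hot surrogate features."""
    return tc.HeadConfig(learning_rate=0.01, max_epochs=300, patience=30, seed=0)


def split_space(landscape, n_train, n_test, seed=1):
    """Disjoint train/test variant lists drawn from the full 2^n space."""
    n = landscape.spec.n_sites
    rng = np.random.default_rng(seed)
    masks = rng.permutation(2**n)
    def variant(m):
        return landscape.variant_from_indices([i for i in range(n) if m >> i & 1])
    train = [variant(m) for m in masks[:n_train]]
    test = [variant(m) for m in masks[n_train:n_train + n_test]]
    return train, test
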