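import numpy as np
import pytest

from sulfsite import seqdata


@pytest.fixture
def small_planted_dataset():
    """300 positive / 600 negative windows with the default K/E planted signal."""
    cfg = seqdata.SyntheticConfig(
        n_positive=300, n_negative=600,
        enrichment_table=seqdata.planted_ke_enrichment(), seed=11)
    return seqdata.generate_synthetic_dataset(cfg)


@pytest.fixture
def null_dataset():
    """Windows with no planted signal (positives and negatives i.i.d.)."""
    cfg = seqdata.SyntheticConfig(n_positive=300, n_negative=300,
                                  enrichment_table={}, seed=12)
    return seqdata.generate_synthetic_dataset(cfg)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs, 20 minority vs 200 majority."""
    rng = np.random.default_rng(1)
    X_min = rng.normal(loc=5.0, scale=0.5, size=(20, 4))
    X_maj = rng.normal(loc=-5.0, scale=0.5, size=(200, 4))
    X = np.vstack([X_min, X_maj])
    y = np.array([1] * 20 + [0] * 200)
    return X, y
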