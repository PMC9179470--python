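import numpy as np
import pytest

from histotex import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 classes x 8 images at side 32 - the smallest trainable fixture set."""
    spec = fixtures.DatasetSpec(
        counts={k: 8 for k in fixtures.TABLE_COUNTS}, side=32, seed=7)
    images, manifest = fixtures.generate_dataset(spec)
    return spec, images, manifest
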