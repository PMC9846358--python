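import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_data():
    """16 small synthetic scenes plus k-means anchors (shared, read-only)."""
    from yolop.train import smoke_dataset

    return smoke_dataset(n_images=16, image_size=96, seed=0)
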