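import numpy as np
import pytest

from cwtdcnn.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-class dataset: 3 subjects/class, 2-3 segments each, fs=250."""
    cfg = SyntheticConfig(
        n_subjects_per_class=3,
        segments_per_subject_range=(2, 3),
        fs=250.0,
        seed=7,
    )
    segments, manifest = generate_dataset(cfg)
    return cfg, segments, manifest


@pytest.fixture
def random_tiles(rng):
    """35 random 100x100 RGB tiles."""
    return [rng.integers(0, 256, size=(100, 100, 3), dtype=np.uint8) for _ in range(35)]
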