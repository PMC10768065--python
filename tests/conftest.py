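import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scene_pairs_64():
    """Eight preprocessed synthetic scenes at 64x64 (shared, read-only)."""
    from weedseg.data_io import SceneSpec, generate_synthetic_dataset, preprocess

    spec = SceneSpec().scaled_to((64, 64))
    train_split = generate_synthetic_dataset(spec, 8, 1, 1, seed=7)[0]
    return [preprocess(img, msk, size=(64, 64)) for img, msk in train_split]


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar ``f()`` w.r.t. the array ``x``
    (mutated in place and restored)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
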