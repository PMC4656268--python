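import numpy as np
import pytest

import pbdkit as pk


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_phantom_set():
    """A small, quick two-class phantom set with extracted features.

    64-pixel images keep unit tests fast; the full-size defaults are
    exercised by the acceptance tests.
    """
    config = pk.PhantomConfig(n_healthy=8, n_pathological=12, size=64, seed=11)
    images, labels, manifest = pk.generate_dataset(config)
    X = np.array([pk.extract_wpte(img, q=0.8).values for img in images])
    return {"images": images, "labels": labels.astype(float), "X": X,
            "manifest": manifest, "config": config}
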