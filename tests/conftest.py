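import numpy as np
import pytest

from btc.phantom import CLASS_NAMES, PhantomSpec, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_set():
    """30 phantoms (10/class) at 64x64, shared by expensive tests."""
    return generate_dataset(n_per_class=10, image_size=64, seed=2024)


@pytest.fixture(scope="session")
def one_phantom_per_class():
    return {
        name: generate_phantom(
            PhantomSpec(image_size=64, class_label=name, seed=5)
        )
        for name in CLASS_NAMES
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
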