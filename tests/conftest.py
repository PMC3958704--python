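import numpy as np
import pytest

import aamfit as A


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Fast generator: 20 landmarks, ~1000-pixel patch, 2+2 modes."""
    return A.SyntheticSpec(n_landmarks=20, target_pixels=1024,
                           n_shape_modes=2, n_texture_modes=2, rng_seed=11)


@pytest.fixture(scope="session")
def small_gen(small_spec):
    return A.make_generator(small_spec)


@pytest.fixture(scope="session")
def small_model(small_gen):
    """Exact (generator-backed) model without a gradient matrix."""
    return A.as_aam_model(small_gen)


@pytest.fixture(scope="session")
def face_spec():
    """The default face regime: 68 landmarks, 4096-pixel patch."""
    return A.SyntheticSpec(rng_seed=5)


@pytest.fixture(scope="session")
def face_gen(face_spec):
    return A.make_generator(face_spec)


@pytest.fixture(scope="session")
def trained_model(face_gen):
    """Model trained on 30 rendered instances of the face generator."""
    images, landmarks, _ = A.make_training_set(face_gen, 30)
    return A.train_aam(images, landmarks, target_pixels=4096, seed=1)
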