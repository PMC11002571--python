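import numpy as np
import pytest

from usformer.phantoms import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


#: small phantom family used by fast tests (scaled-down grid)
SMALL_SPEC = PhantomSpec(
    shape=(32, 32, 16),
    body_semiaxes_ij=(4.0, 6.5),
    body_semiaxes_k=(2.5, 4.0),
    tube_radius_range=(1.0, 1.6),
    tube_length_range=(5, 9),
    foreground_bounds=(0.005, 0.08),
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(SMALL_SPEC, seed=11)


def random_blob(rng: np.random.Generator, shape=(10, 10, 10), p=0.3) -> np.ndarray:
    """Random binary mask with at least one foreground voxel."""
    m = (rng.random(shape) < p).astype(np.uint8)
    if not m.any():
        m[tuple(d // 2 for d in shape)] = 1
    return m
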