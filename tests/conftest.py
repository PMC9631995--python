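import numpy as np
import pytest

from oxoquartet import (
    BaseId,
    build_quartet,
    get_template,
    make_sequence_core,
)


@pytest.fixture(scope="session")
def g_template():
    return get_template(BaseId.G)


@pytest.fixture(scope="session")
def oxog_template():
    return get_template(BaseId.OXOG)


@pytest.fixture(scope="session")
def oxog_quartet(oxog_template):
    """oxoG-quartet fitted to the no-cation H...A targets."""
    return build_quartet(oxog_template)


@pytest.fixture(scope="session")
def g_quartet(g_template):
    """Canonical G-quartet at the experimental reference ring size."""
    return build_quartet(g_template, mode="ring_size", value=3.15)


@pytest.fixture(scope="session")
def odn4_core():
    """Central-oxoG analogue core: T G G X G T."""
    return make_sequence_core("TGGXGT")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
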