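import numpy as np
import pytest

from sonoskin import PhantomSpec, SkinLayers, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def nevus_sample(default_spec):
    return generate_phantom(default_spec, "nevus", seed=11)


@pytest.fixture(scope="session")
def bcc_sample(default_spec):
    return generate_phantom(default_spec, "BCC", seed=11)


@pytest.fixture(scope="session")
def mm_sample(default_spec):
    return generate_phantom(default_spec, "MM", seed=11)


def layers_of(sample) -> SkinLayers:
    """Ground-truth layer bands of a phantom sample as a SkinLayers object."""
    return SkinLayers(*sample.truth_layers)


@pytest.fixture()
def flat_layers():
    """Uniform layer geometry for hand-built 128x160 test images."""
    w = 160
    return SkinLayers(epidermis_top=np.full(w, 12), dermis_top=np.full(w, 20),
                      dermis_bottom=np.full(w, 128))


def square_mask(shape=(128, 160), top=60, left=70, size=20):
    m = np.zeros(shape, dtype=bool)
    m[top:top + size, left:left + size] = True
    return m
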