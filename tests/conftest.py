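import numpy as np
import pytest

from tissueseg.core import LevelRef
from tissueseg.synthetic import SyntheticSpec, generate

#: a small pyramid whose single blob survives the 250 µm cleanup at its
#: 2 µm base spacing (blob diameters 180-260 px = 360-520 µm)
SMALL_SPEC = SyntheticSpec(
    canvas=512,
    spacing=2.0,
    n_levels=3,
    n_blobs=1,
    blob_diameter_px=(180, 260),
    seed=42,
)


@pytest.fixture(scope="session")
def small_synth():
    return generate(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_pyramid(small_synth):
    return small_synth[0]


@pytest.fixture(scope="session")
def small_annotations(small_synth):
    return small_synth[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def level1um():
    return LevelRef(0, 1.0)
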