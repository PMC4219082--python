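import numpy as np
import pytest

from ctdens.image_io import CTSlice
from ctdens.phantom import PhantomSpec, make_phantom
from ctdens.segmentation import segment_slice


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def clean_phantom():
    """Intact phantom (no defects or artifacts), full 512 grid."""
    return make_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def busy_phantom():
    """Phantom with fracture, craniotomy, EVD, air bubble and gantry."""
    spec = PhantomSpec(
        seed=12,
        fractures=((300.0, 15.0),),
        craniotomy=((150.0, 50.0),),
        evd=True,
        air_bubble=True,
        gantry=True,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def clean_seg(clean_phantom):
    slc, _ = clean_phantom
    return segment_slice(slc)


@pytest.fixture(scope="session")
def busy_seg(busy_phantom):
    slc, _ = busy_phantom
    return segment_slice(slc)


@pytest.fixture()
def all_air_slice():
    return CTSlice(pixels=np.full((64, 64), -1000, dtype=np.int32))
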