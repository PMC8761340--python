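import numpy as np
import pytest

from mvseg.phantom import PhantomConfig, generate_case
from mvseg.volume_io import LabelMask, Volume


@pytest.fixture(scope="session")
def small_phantom():
    """One 48^3 phantom with a 4 cm^3 tumor, aligned to the template frame."""
    cfg = PhantomConfig(
        shape=(48, 48, 48),
        tumor_volume_cm3=4.0,
        misalign_mm=0.0,
        misalign_deg=0.0,
        noise_sd=2.0,
        seed=11,
    )
    return generate_case(cfg)


@pytest.fixture(scope="session")
def misaligned_phantom():
    """A 64^3 phantom with inter-sequence misalignment and a subject pose."""
    cfg = PhantomConfig(
        tumor_volume_cm3=10.0,
        misalign_mm=3.0,
        misalign_deg=3.0,
        subject_misalign_mm=4.0,
        subject_misalign_deg=4.0,
        noise_sd=2.0,
        t1gad_missing_probability=0.0,
        seed=5,
    )
    return generate_case(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def random_volume(rng, shape=(8, 8, 8), affine=None):
    return Volume(rng.random(shape), np.eye(4) if affine is None else affine)


def random_mask(rng, shape=(8, 8, 8), p=0.3):
    return LabelMask((rng.random(shape) < p).astype(np.uint8), np.eye(4))
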