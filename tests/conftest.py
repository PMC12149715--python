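import numpy as np
import pytest

from csiseg.io_preproc import CTVolume, LabelSet
from csiseg.phantom import PhantomSpec, generate_cohort, generate_phantom

#: compact canvas used by unit tests; ages >= 8 keep the smallest organs
#: rasterizable at this resolution
SMALL_CANVAS = (64, 64, 96)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic phantom (age 10) on the compact canvas."""
    return generate_phantom(PhantomSpec(age=10.0, canvas=SMALL_CANVAS, seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Four deterministic phantoms on the compact canvas."""
    return generate_cohort(4, (8.0, 16.0), seed=5, canvas=SMALL_CANVAS)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(10, 12, 14), lo=-1000.0, hi=2000.0) -> CTVolume:
    return CTVolume(rng.uniform(lo, hi, size=shape).astype(np.float32),
                    (1.5, 1.0, 1.0), id="rand")


def random_mask(rng, shape, p=0.3) -> np.ndarray:
    return rng.uniform(size=shape) < p
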