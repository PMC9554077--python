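import numpy as np
import pytest

from bdseg.phantom import PhantomSpec, make_phantom


def small_spec(seed: int = 0, **kwargs) -> PhantomSpec:
    """32-cube phantom spec used by fast tests."""
    defaults = dict(shape=(32, 32, 32), breast_radius_range=(5.0, 6.2),
                    muscle_jut=1.0, seed=seed)
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def default_phantom():
    """One standard-size phantom shared across read-only tests."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(small_spec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom
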