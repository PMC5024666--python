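import numpy as np
import pytest

from illumdisc import illuminants as il
from illumdisc import scene as sc


@pytest.fixture(scope="session")
def led_basis():
    return il.make_led_basis()


@pytest.fixture(scope="session")
def all_series(led_basis):
    """Full 51-step comparison series for all four chromatic directions."""
    return {d: il.generate_series(d, led_basis) for d in il.DIRECTIONS}


@pytest.fixture(scope="session")
def target_spectrum(led_basis):
    return il.synthesize_target(led_basis)


@pytest.fixture(scope="session")
def small_scene():
    return sc.generate_mondrian((64, 64), n_rects=800, rng=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
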