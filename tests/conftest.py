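import numpy as np
import pytest

from gradiq import FixtureSpec, build_kernel_bank, make_natural_fixture, make_screen_fixture


@pytest.fixture(scope="session")
def bank():
    return build_kernel_bank(5)


@pytest.fixture(scope="session")
def screen_image():
    return make_screen_fixture(FixtureSpec(128, 128, seed=7))


@pytest.fixture(scope="session")
def natural_image():
    return make_natural_fixture(128, 128, 2.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
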