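import numpy as np
import pytest

import beltlink as bl


@pytest.fixture(scope="session")
def wt_belt():
    """Wild-type double belt at the measured circumference (effective rise)."""
    return bl.build_double_belt(243, 300.0)


@pytest.fixture(scope="session")
def chemistries():
    return bl.builtin_chemistries()


@pytest.fixture(scope="session")
def toy_walk():
    """A compact random-walk reference with a mixed sequence."""
    return bl.make_toy_reference(120, "random-walk", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
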