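import numpy as np
import pytest

from infogrowth import EnvironmentSpec, to_joint


@pytest.fixture
def env27():
    """Binary environment with a moderately informative signal."""
    return EnvironmentSpec(l=2, p=0.7)


@pytest.fixture
def joint27(env27):
    return to_joint(env27)


@pytest.fixture
def rng():
    return np.random.default_rng(20230322)
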