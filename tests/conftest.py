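import numpy as np
import pytest

from chromofiber.nucleosome_geometry import make_ideal_core


@pytest.fixture(scope="session")
def core():
    return make_ideal_core()


@pytest.fixture(scope="session")
def rest_steps():
    def make(n):
        return np.tile([34.5, 0.0, 0.0, 0.0, 0.0, 3.35], (n, 1))

    return make
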