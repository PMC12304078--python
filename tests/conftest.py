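import numpy as np
import pytest

from scorpcam.spectral import build_visual_system, load_illuminant


@pytest.fixture(scope="session")
def scorpionfish():
    return build_visual_system("scorpaena_porcus")


@pytest.fixture(scope="session")
def triplefin():
    return build_visual_system("tripterygion_delaisi")


@pytest.fixture(scope="session")
def d65():
    return load_illuminant("d65")


@pytest.fixture
def rng():
    return np.random.default_rng(20230601)
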