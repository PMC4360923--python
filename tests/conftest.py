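import numpy as np
import pytest

from psnlm import PhantomSpec, build_vst, generate_phantom


@pytest.fixture(scope="session")
def vst_table():
    """Default stabilizer table, built once for the whole suite."""
    return build_vst()


@pytest.fixture(scope="session")
def t1_phantom_64():
    """64³ T1-style phantom (t = 150), fixed geometry seed."""
    return generate_phantom(PhantomSpec(shape=(64, 64, 64), modality="T1", geometry_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
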