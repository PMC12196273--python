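import numpy as np
import pytest

from ivivr import simulate as sim


@pytest.fixture(scope="session")
def small_shape():
    """Desk-scale frame size used for most tests (full aspect preserved)."""
    return (56, 48)


@pytest.fixture(scope="session")
def ir_study(small_shape):
    return sim.generate_default_study("IR500", seed=11, shape=small_shape)


@pytest.fixture(scope="session")
def xr_study(small_shape):
    return sim.generate_default_study("XR750", seed=11, shape=small_shape)


@pytest.fixture(scope="session")
def ir_study_noisefree(small_shape):
    return sim.generate_default_study("IR500", seed=11, shape=small_shape,
                                      noise_fraction=0.0)


@pytest.fixture(scope="session")
def xr_study_noisefree(small_shape):
    return sim.generate_default_study("XR750", seed=11, shape=small_shape,
                                      noise_fraction=0.0)
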