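import numpy as np
import pytest

from bst1map.bloch_siegert import PulseSpec, build_lookup_table
from bst1map.synthetic import PhantomSpec, make_breast_phantom, make_gel_phantom


@pytest.fixture(scope="session")
def gel_gt():
    """Default 8-tube gel phantom with the left-right B1 ramp."""
    return make_gel_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def gel_gt_uniform():
    """8-tube gel phantom with a homogeneous transmit field (f = 1)."""
    return make_gel_phantom(PhantomSpec(b1_field="uniform", b1_range=(1.0, 1.0)))


@pytest.fixture(scope="session")
def breast_gt():
    return make_breast_phantom(PhantomSpec(kind="breast", grid_shape=(1, 64, 64)))


@pytest.fixture(scope="session")
def default_pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def default_lookup(default_pulse):
    return build_lookup_table(default_pulse)
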