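import numpy as np
import pytest

from atlasforge.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom32():
    """Small symmetric phantom: (intensity, annotation, mask) at 32³."""
    return make_phantom(PhantomSpec(seed=11, shape=(32, 32, 32), n_regions=3))


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom(PhantomSpec(seed=12, shape=(48, 48, 48), n_regions=4))


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomSpec(seed=13, shape=(64, 64, 64), n_regions=4))
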