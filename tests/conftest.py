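import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def tiny_pair():
    """A small synthetic registration pair (48x48, 3-voxel displacement)."""
    from splitreg.synthetic import SyntheticSpec, make_pair

    spec = SyntheticSpec(shape=(48, 48), max_displacement=3.0, smoothness_sigma=4.0,
                         n_regions=4, noise_sigma=0.01)
    return make_pair(spec, np.random.default_rng(7))
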