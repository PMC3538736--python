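import numpy as np
import pytest

from renperf import synthetic


@pytest.fixture(scope="session")
def small_spec() -> synthetic.PhantomSpec:
    """Compact 64x64 phantom for fast unit tests."""
    return synthetic.PhantomSpec(
        grid_shape=(64, 64),
        kidney_left=synthetic.Ellipse(center=(36.0, 19.0), axes=(13.0, 8.5)),
        kidney_right=synthetic.Ellipse(center=(36.0, 45.0), axes=(13.0, 8.5)),
        cortex_thickness=3.0,
        aorta_center=(12.0, 32.0),
        aorta_radius=2.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return synthetic.make_phantom(small_spec)


@pytest.fixture(scope="session")
def default_spec() -> synthetic.PhantomSpec:
    """Full-size 128x128 phantom at the study conditions."""
    return synthetic.PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return synthetic.make_phantom(default_spec)


@pytest.fixture(scope="session")
def noise_free_asl(small_truth, small_spec):
    return synthetic.simulate_asl(small_truth, small_spec)


@pytest.fixture(scope="session")
def noise_free_dce(small_truth):
    return synthetic.simulate_dce(
        small_truth, synthetic.AIFModel(), synthetic.ResidueModel()
    )
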