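import numpy as np
import pytest

from ihmt.simulate import PhantomSpec
from ihmt.volumes import Volume3D


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A reduced study spec for fast image-level tests."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        n_subjects=2,
        noise_sigma=0.0,
        sd_subject=0.0,
        sd_scan=0.0,
        angle_slope=0.0,
        seed=7,
    )


@pytest.fixture
def unit_volume() -> Volume3D:
    rng = np.random.default_rng(0)
    return Volume3D(rng.uniform(1.0, 2.0, size=(6, 5, 4)), np.diag([2.0, 2.0, 2.0, 1.0]))
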