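"""Shared fixtures: phantoms and their segmentation results.

The full-size phantoms and pipeline runs are session-scoped so the
segmentation suite and the acceptance checks share one computation each.
"""

import numpy as np
import pytest

from pulmocad.lungseg import segment_lungs
from pulmocad.phantom import PhantomSpec, default_phantom_spec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless study-default phantom: not fused, one interior 10 mm nodule."""
    return generate_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def fused_phantom():
    return generate_phantom(default_phantom_spec(fused=True))


@pytest.fixture(scope="session")
def notch_phantom():
    return generate_phantom(default_phantom_spec(pleural_notch=True))


@pytest.fixture(scope="session")
def default_segmentation(default_phantom):
    vol, _ = default_phantom
    return segment_lungs(vol)


@pytest.fixture(scope="session")
def fused_segmentation(fused_phantom):
    vol, _ = fused_phantom
    return segment_lungs(vol)


@pytest.fixture(scope="session")
def notch_segmentation(notch_phantom):
    vol, _ = notch_phantom
    return segment_lungs(vol)


def small_spec(**overrides) -> PhantomSpec:
    """A half-size phantom for cheap per-test pipeline runs."""
    defaults = dict(
        shape=(40, 80, 100),
        body_center_xy=(50.0, 41.0),
        body_semiaxes_xy=(43.0, 30.0),
        lung_centers_x=(30.0, 70.0),
        lung_center_yz=(40.0, 20.0),
        lung_semiaxes=(16.0, 20.0, 16.0),
        trachea_radius=2.5,
        bronchus_radius=1.5,
        airway_wall_mm=2.0,
        carina_z=22.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
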