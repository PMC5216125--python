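import numpy as np
import pytest

from mitogold.geometry import MitosomeProfile, Point2D


@pytest.fixture
def circle_profile() -> MitosomeProfile:
    """Circular profile whose inner aspect is a 50-nm-radius circle."""
    return MitosomeProfile(
        profile_id="c0",
        field_id="F0",
        center=Point2D(0.0, 0.0),
        semi_major_outer=65.0,
        semi_minor_outer=65.0,
        orientation=0.0,
        membrane_inset=15.0,
    )


@pytest.fixture
def ellipse_profile() -> MitosomeProfile:
    """Elliptical profile with inner-aspect semi-axes (63.5, 40) nm."""
    return MitosomeProfile(
        profile_id="e0",
        field_id="F0",
        center=Point2D(0.0, 0.0),
        semi_major_outer=78.5,
        semi_minor_outer=55.0,
        orientation=0.0,
        membrane_inset=15.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231201)
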