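import numpy as np
import pytest

from capsulesim import (CapsuleShape, DragModel, StimulusParams, TissueParams,
                        preset_config)


@pytest.fixture
def shape_type1():
    """Type-1 capsule: r = 3 mm, R = 5.5 mm, alpha = 0.3/mm, L = 26 mm."""
    return CapsuleShape.from_mm(3.0, 5.5, 0.3, 26.0)


@pytest.fixture
def tissue_default():
    """Bundled default tissue constants."""
    return TissueParams.from_mm(8.0, 0.6, stress_scale=5.0, mu=0.1)


@pytest.fixture
def stim_default():
    """6 V / 10 Hz / 5 ms stimulus, electrode 5 mm from the rear edge."""
    return StimulusParams.from_config_units(6.0, 10.0, 5.0, 5.0)


@pytest.fixture
def drag_default():
    return DragModel.constant(0.5)  # N s/m == mN s/mm


@pytest.fixture(scope="session")
def type1_config():
    return preset_config("type1")
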