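import numpy as np
import pytest

from tminav import DisplayConfig, ToolGeometry, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tool():
    return ToolGeometry(tip_offset=(0.0, 0.0, 100.0), shaft_axis=(0.0, 0.0, 1.0))


@pytest.fixture
def traj_z():
    """Planned path straight along +z from the origin."""
    return Trajectory(id="Th12-L", entry=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0), target_depth=40.0)


@pytest.fixture
def cfg():
    return DisplayConfig(tolerance_deg=1.0, theta_max_deg=45.0)
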