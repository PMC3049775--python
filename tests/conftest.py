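import numpy as np
import pytest

from helix_unravel.builder import build_ideal_helix
from helix_unravel.topology import build_topology
from helix_unravel.trajectory import Trajectory


@pytest.fixture(scope="session")
def wt_topology():
    return build_topology("WT", "+")


@pytest.fixture(scope="session")
def ideal_helix(wt_topology):
    return build_ideal_helix(wt_topology)


@pytest.fixture()
def helix_trajectory(wt_topology, ideal_helix):
    """Five identical helix frames at 10 ps stride."""
    coords = np.repeat(ideal_helix.coords[None], 5, axis=0)
    return Trajectory(wt_topology, coords, stride_ps=10.0)
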