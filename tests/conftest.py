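import numpy as np
import pytest

import reefspectra as rs


@pytest.fixture(scope="session")
def grid():
    """The reference body-mass grid."""
    return rs.SizeGrid.build()


@pytest.fixture(scope="session")
def coarse_grid():
    """A coarser grid for fast dynamics tests."""
    return rs.SizeGrid.build(n_bins=60)


@pytest.fixture()
def census():
    """A hand-built healthy-reef crevice census, 5-60 cm classes."""
    edges = np.arange(5.0, 65.0, 5.0)
    dens = 2.0 * 0.6 ** np.arange(edges.size - 1)
    return rs.CreviceDistribution("healthy_reef_a", edges, dens)


@pytest.fixture()
def supplement():
    """A mangrove supplement at the group-mean densities."""
    return rs.NurserySupplement("mangrove_mean", 0.96, 0.10)
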