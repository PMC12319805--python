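"""Shared fixtures: a small synthetic cord and paradigms.

The small grid (24x24x21 voxels, seven 3-slice levels) keeps per-test
simulation and GLM fits fast while preserving all geometric structure
(cord/CSF masks, hemicords, level boundaries).
"""

import numpy as np
import pytest

from lumbocord.cord_geometry import LEVEL_NAMES, hemicord_partition
from lumbocord.synthetic_data import make_cord_geometry, make_paradigm


@pytest.fixture(scope="session")
def small_geometry():
    return make_cord_geometry(
        grid_shape=(24, 24, 21),
        voxel_size=(1.1, 1.1, 3.0),
        cord_radius_mm=4.0,
        level_extents=[3] * len(LEVEL_NAMES),
    )


@pytest.fixture(scope="session")
def small_partition(small_geometry):
    return hemicord_partition(small_geometry.cord_mask, small_geometry.centerline)


@pytest.fixture(scope="session")
def active_paradigm():
    return make_paradigm("active", tr=2.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
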