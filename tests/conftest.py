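import numpy as np
import pytest

from limbiccog.imaging_io import BoldSeries, BrainMask
from limbiccog.synthetic_cohort import CohortDesign, make_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_design():
    return CohortDesign(
        n_bd=4, n_hc=4, grid_shape=(6, 6, 6), n_timepoints=40, n_regions=8, seed=7
    )


@pytest.fixture
def small_parcellation(small_design):
    return make_parcellation(small_design)


@pytest.fixture
def random_bold(rng):
    data = rng.standard_normal((4, 4, 4, 50))
    return BoldSeries("sub-rand", data, voxel_size_mm=[3.0, 3.0, 3.0], tr_seconds=2.0)


@pytest.fixture
def full_mask():
    return BrainMask(np.ones((4, 4, 4), dtype=bool))
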