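import numpy as np
import pytest

from igtnet.synthetic import CommunitySpec, make_toy_atlas
from igtnet.timeseries import VoxelTimeSeriesSet


@pytest.fixture(scope="session")
def small_atlas():
    """12^3 grid, three 40-voxel communities (one DMN-like, one FPN-like)."""
    return make_toy_atlas(
        (12, 12, 12),
        [
            CommunitySpec(label=1, name="dmn-like", count=40, network="DMN"),
            CommunitySpec(label=2, name="fpn-like", count=40, network="FPN"),
            CommunitySpec(label=3, name="other", count=40),
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20160627)


def make_ts(data, tr=2.0):
    """Wrap a bare (voxels, timepoints) array in a VoxelTimeSeriesSet."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    vox = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return VoxelTimeSeriesSet(
        data=data, voxel_index=vox, labels=np.ones(n, int), tr_seconds=tr
    )


def random_adjacency(rng, n, p=0.2):
    """Symmetric loop-free 0/1 matrix."""
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T
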