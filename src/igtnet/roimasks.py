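"""DMN and FPN region-of-interest masks.

Regional summaries use spherical seeds at canonical MNI coordinates for the
default-mode network (vmPFC, bilateral inferior parietal cortex,
precuneus/PCC) and the fronto-parietal network (bilateral VLPFC and DLPFC,
bilateral superior parietal cortex, dACC), 10 mm radius each.  Seeds are
shipped as a CSV table, merged per network and intersected with the
gray-matter mask; the synthetic atlas carries "virtual MNI" coordinates so
the same table works in toy space.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .volumes import LabeledVolume


@dataclass(frozen=True)
class RoiSpec:
    """One spherical seed region."""

    name: str
    network: str  # "DMN" or "FPN"
    center: tuple[float, float, float]  # mm
    radius: float = 10.0  # mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI {self.name!r}: radius must be positive")


@dataclass
class NetworkMask:
    """Union of a network's member ROI spheres, restricted to gray matter."""

    network: str
    mask: np.ndarray  # boolean volume
    member_rois: list[RoiSpec]


def load_roi_table(path) -> list[RoiSpec]:
    """Read a (name, network, x, y, z, radius) CSV into RoiSpecs."""
    df = pd.read_csv(path)
    return [
        RoiSpec(
            name=str(r.name),
            network=str(r.network),
            center=(float(r.x), float(r.y), float(r.z)),
            radius=float(r.radius),
        )
        for r in df.itertuples(index=False)
    ]


def reference_roi_table() -> list[RoiSpec]:
    """The packaged seed table: 7 FPN ROIs and 4 DMN ROIs."""
    with resources.files("igtnet.data").joinpath("roi_table.csv").open() as fh:
        return load_roi_table(fh)


def sphere_mask(spec: RoiSpec, grid: LabeledVolume) -> np.ndarray:
    """Boolean volume: voxel centers within ``spec.radius`` mm of the center.

    The boundary is inclusive.  Raises if the sphere captures no voxel
    (entirely outside the grid).
    """
    idx = np.indices(grid.shape).reshape(3, -1).T
    coords = grid.coordinates(idx)
    d = np.linalg.norm(coords - np.asarray(spec.center, float), axis=1)
    mask = (d <= spec.radius).reshape(grid.shape)
    if not mask.any():
        raise ValueError(f"ROI {spec.name!r} lies entirely outside the grid")
    return mask


def merge_network_mask(
    specs: list[RoiSpec], grid: LabeledVolume, gm_mask: np.ndarray
) -> NetworkMask:
    """Union of same-network ROI spheres intersected with the gray-matter mask."""
    networks = {s.network for s in specs}
    if len(networks) != 1:
        raise ValueError(f"specs span multiple networks: {sorted(networks)}")
    union = np.zeros(grid.shape, dtype=bool)
    for spec in specs:
        union |= sphere_mask(spec, grid)
    mask = union & np.asarray(gm_mask, dtype=bool)
    if not mask.any():
        raise ValueError(
            f"network {networks.pop()!r} mask is empty after gray-matter restriction"
        )
    return NetworkMask(network=specs[0].network, mask=mask, member_rois=list(specs))
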