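"""Voxel time-series container and confound design matrices."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class VoxelTimeSeriesSet:
    """Voxels x timepoints matrix with voxel bookkeeping.

    ``data`` rows align with ``voxel_index`` (3-D grid coordinate of each
    voxel) and ``labels`` (atlas code per voxel).  ``kept_volume_index``
    tracks which original acquisition volumes survive discarding and
    scrubbing, so downstream stages can align external per-volume records
    (motion traces) with the retained timepoints.
    """

    data: np.ndarray  # (n_voxels, n_timepoints)
    voxel_index: np.ndarray  # (n_voxels, 3) int grid coordinates
    labels: np.ndarray  # (n_voxels,) int atlas codes
    tr_seconds: float
    kept_volume_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be (voxels, timepoints)")
        if len(self.voxel_index) != self.n_voxels or len(self.labels) != self.n_voxels:
            raise ValueError("voxel_index/labels must align with data rows")
        if self.kept_volume_index is None:
            self.kept_volume_index = np.arange(self.n_timepoints)
        self.kept_volume_index = np.asarray(self.kept_volume_index, dtype=int)
        if len(self.kept_volume_index) != self.n_timepoints:
            raise ValueError("kept_volume_index must align with timepoints")
        if np.any(np.diff(self.kept_volume_index) <= 0):
            raise ValueError("kept_volume_index must be strictly increasing")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, kept: np.ndarray | None = None):
        """Copy with new data (and optionally new kept-volume index)."""
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            kept_volume_index=self.kept_volume_index if kept is None else kept,
        )

    def select_voxels(self, keep: np.ndarray) -> "VoxelTimeSeriesSet":
        keep = np.asarray(keep)
        return replace(
            self,
            data=self.data[keep],
            voxel_index=self.voxel_index[keep],
            labels=self.labels[keep],
        )

    def select_timepoints(self, keep: np.ndarray) -> "VoxelTimeSeriesSet":
        keep = np.asarray(keep)
        return self.with_data(self.data[:, keep], kept=self.kept_volume_index[keep])


@dataclass
class ConfoundSet:
    """Timepoints x regressors nuisance design with named columns."""

    columns: np.ndarray  # (n_timepoints, n_regressors)
    names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[1] != len(self.names):
            raise ValueError("one name per confound column required")

    @property
    def n_timepoints(self) -> int:
        return self.columns.shape[0]

    def subset_timepoints(self, keep: np.ndarray) -> "ConfoundSet":
        return ConfoundSet(self.columns[np.asarray(keep)], list(self.names))
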