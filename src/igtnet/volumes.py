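"""Labeled toy brain volumes.

A :class:`LabeledVolume` is the package's stand-in for an anatomical
parcellation plus tissue segmentation: a 3-D integer label grid with an
affine mapping voxel indices to spatial (mm) coordinates.  Label semantics
(tissue class, functional community membership) live in a label table so a
real atlas volume can be plugged in by supplying its own table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: tissue classes a label may carry
TISSUES = ("gray", "white", "csf")


@dataclass(frozen=True)
class LabelInfo:
    """Semantics of one integer label code."""

    name: str
    tissue: str  # one of TISSUES
    network: str | None = None  # optional community tag, e.g. "DMN" / "FPN"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for label {self.name!r}")


@dataclass
class LabeledVolume:
    """Integer label grid with voxel->mm affine.

    Parameters
    ----------
    labels
        3-D int array; 0 is background, every nonzero code must appear in
        ``label_table``.  A voxel carries exactly one code, so tissue classes
        are mutually exclusive per voxel by construction.
    affine
        4x4 voxel-index -> mm mapping (NIfTI convention).
    label_table
        code -> :class:`LabelInfo`.
    """

    labels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, LabelInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got shape {self.labels.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label table")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def coordinates(self, index: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) mm coordinates."""
        index = np.atleast_2d(index)
        hom = np.c_[index, np.ones(len(index))]
        return (self.affine @ hom.T).T[:, :3]

    # -- label queries ----------------------------------------------------
    def codes_for(self, tissue: str) -> list[int]:
        return [c for c, info in self.label_table.items() if info.tissue == tissue]

    def tissue_mask(self, tissue: str) -> np.ndarray:
        """Boolean volume of voxels whose label carries the given tissue."""
        codes = self.codes_for(tissue)
        return np.isin(self.labels, codes)

    def network_codes(self, network: str) -> list[int]:
        return [
            c for c, info in self.label_table.items() if info.network == network
        ]

    # -- I/O --------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int16), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_labeled_volume(path, label_table: dict[int, LabelInfo]) -> LabeledVolume:
    """Read a label volume from NIfTI, attaching externally supplied semantics."""
    img = nib.load(str(path))
    return LabeledVolume(
        labels=np.asarray(img.dataobj).astype(int),
        affine=img.affine,
        label_table=label_table,
    )
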