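"""Time-series cleaning chain.

Order of operations (configurable between the last two): discard initial
volumes -> motion scrubbing -> gray-matter masking -> band-pass filtering
-> nuisance regression (WM mean, CSF mean, 6 motion parameters, global
gray-matter mean).  Confound columns are band-passed identically to the
data before regression so removed frequencies are not reintroduced.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .timeseries import ConfoundSet, VoxelTimeSeriesSet
from .volumes import LabeledVolume

#: Power-convention head radius (mm) converting rotations to displacement
FD_HEAD_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def build_gray_matter_mask(
    gm: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    atlas: LabeledVolume,
    wm_threshold: float = 0.99,
) -> np.ndarray:
    """Analysis mask: whole-brain support ∩ atlas gray labels, minus near-pure WM.

    ``gm``/``wm``/``csf`` are tissue probability (or indicator) volumes.  The
    whole-brain mask is the binarized sum of the three segments; it is
    intersected with the atlas's gray labels, then voxels whose WM
    probability reaches ``wm_threshold`` are subtracted.
    """
    gm, wm, csf = (np.asarray(v, dtype=float) for v in (gm, wm, csf))
    shapes = {gm.shape, wm.shape, csf.shape, atlas.shape}
    if len(shapes) != 1:
        raise ValueError(f"volume shapes differ: {sorted(shapes)}")
    whole_brain = (gm + wm + csf) > 0
    return whole_brain & atlas.tissue_mask("gray") & ~(wm >= wm_threshold)


def tissue_probability_volumes(atlas: LabeledVolume) -> tuple[np.ndarray, ...]:
    """Indicator GM/WM/CSF volumes from a labeled atlas (synthetic segmentation)."""
    return (
        atlas.tissue_mask("gray").astype(float),
        atlas.tissue_mask("white").astype(float),
        atlas.tissue_mask("csf").astype(float),
    )


def apply_mask(ts: VoxelTimeSeriesSet, mask: np.ndarray) -> VoxelTimeSeriesSet:
    """Keep only voxels whose grid coordinate is True in ``mask``. Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    keep = mask[tuple(ts.voxel_index.T)]
    if not keep.any():
        raise ValueError("mask retains no voxels")
    return ts.select_voxels(keep)


# ---------------------------------------------------------------------------
# volume discarding and scrubbing
# ---------------------------------------------------------------------------

def discard_initial(ts: VoxelTimeSeriesSet, n: int = 10) -> VoxelTimeSeriesSet:
    """Drop the first ``n`` timepoints (scanner equilibration volumes)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= ts.n_timepoints:
        raise ValueError(f"cannot discard {n} of {ts.n_timepoints} volumes")
    return ts.select_timepoints(np.arange(n, ts.n_timepoints))


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """FD(t) = sum |Δ translations| + head_radius * sum |Δ rotations|.

    ``motion`` is (n_volumes, 6): translations in mm then rotations in
    radians.  FD of the first volume is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (n_volumes, 6)")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + FD_HEAD_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return np.r_[0.0, fd]


def scrub_volumes(
    ts: VoxelTimeSeriesSet,
    motion: np.ndarray,
    fd_threshold: float = 0.5,
) -> tuple[VoxelTimeSeriesSet, np.ndarray]:
    """Remove volumes whose framewise displacement exceeds ``fd_threshold`` mm.

    ``motion`` is indexed by *original* volume number; rows are selected via
    ``ts.kept_volume_index`` so scrubbing composes with volume discarding.
    Returns the scrubbed series and the indices (into the current series) of
    removed volumes.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] <= ts.kept_volume_index.max():
        raise ValueError(
            f"motion trace has {motion.shape[0]} rows; series references "
            f"volume {ts.kept_volume_index.max()}"
        )
    fd = framewise_displacement(motion[ts.kept_volume_index])
    bad = np.flatnonzero(fd > fd_threshold)
    if len(bad) == ts.n_timepoints:
        raise ValueError("scrubbing removed every volume (degenerate series)")
    keep = np.setdiff1d(np.arange(ts.n_timepoints), bad)
    return ts.select_timepoints(keep), bad


# ---------------------------------------------------------------------------
# filtering and regression
# ---------------------------------------------------------------------------

def bandpass(
    ts: VoxelTimeSeriesSet,
    low: float = 0.009,
    high: float = 0.08,
    order: int = 2,
) -> VoxelTimeSeriesSet:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    return ts.with_data(
        _bandpass_array(ts.data, ts.tr_seconds, low=low, high=high, order=order)
    )


def _bandpass_array(
    data: np.ndarray, tr_seconds: float, low: float, high: float, order: int = 2
) -> np.ndarray:
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyquist} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr_seconds,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def extract_confounds(
    ts: VoxelTimeSeriesSet,
    motion: np.ndarray,
    gm_mask: np.ndarray | None = None,
    include_global: bool = True,
) -> ConfoundSet:
    """Assemble WM mean, CSF mean, 6 motion parameters and the global signal.

    The global signal is the mean over the analysis (gray-matter) mask if
    given, else over all gray-labeled voxels present in the series.  Motion
    rows are aligned via ``kept_volume_index``.
    """
    motion = np.asarray(motion, dtype=float)
    cols, names = [], []
    labels = ts.labels
    # tissue means need the label table only through tissue conventions:
    # WM/CSF slabs carry dedicated codes in the synthetic atlas; callers with
    # a real segmentation can pass precomputed confounds instead.
    for tissue_codes, name in ((_codes(ts, "white"), "wm_mean"),
                               (_codes(ts, "csf"), "csf_mean")):
        rows = np.isin(labels, tissue_codes)
        if rows.any():
            cols.append(ts.data[rows].mean(axis=0))
            names.append(name)
    mot = motion[ts.kept_volume_index]
    cols.extend(mot.T)
    names.extend([f"motion_{ax}" for ax in
                  ("tx", "ty", "tz", "rx", "ry", "rz")])
    if include_global:
        if gm_mask is not None:
            gray_rows = np.asarray(gm_mask, dtype=bool)[tuple(ts.voxel_index.T)]
        else:
            gray_rows = np.isin(labels, _codes(ts, "gray"))
        if not gray_rows.any():
            raise ValueError("no gray voxels available for the global signal")
        cols.append(ts.data[gray_rows].mean(axis=0))
        names.append("global_mean")
    return ConfoundSet(columns=np.column_stack(cols), names=names)


def _codes(ts: VoxelTimeSeriesSet, tissue: str) -> list[int]:
    table = ts.provenance.get("label_table")
    if table is not None:
        return [c for c, info in table.items() if info.tissue == tissue]
    # synthetic convention: 91 = white slab, 92 = csf slab, rest gray
    if tissue == "white":
        return [91]
    if tissue == "csf":
        return [92]
    return [c for c in np.unique(ts.labels) if c not in (0, 91, 92)]


def nuisance_regress(
    ts: VoxelTimeSeriesSet, confounds: ConfoundSet
) -> VoxelTimeSeriesSet:
    """Per-voxel OLS residuals after projecting out confounds (plus intercept).

    Residuals are exactly orthogonal to every confound column.  Rank-deficient
    designs are rejected with the names of the collinear columns.
    """
    if confounds.n_timepoints != ts.n_timepoints:
        raise ValueError(
            f"confounds have {confounds.n_timepoints} timepoints, "
            f"series has {ts.n_timepoints}"
        )
    X = np.column_stack([np.ones(ts.n_timepoints), confounds.columns])
    names = ["intercept", *confounds.names]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient confound design; collinear: {collinear}")
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    return ts.with_data(ts.data - (X @ beta).T)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedily identify columns not adding rank."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    return bad


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess_block(
    ts: VoxelTimeSeriesSet,
    motion: np.ndarray,
    gm_mask: np.ndarray,
    n_discard: int = 10,
    fd_threshold: float = 0.5,
    low: float = 0.009,
    high: float = 0.08,
    include_global: bool = True,
    filter_before_regression: bool = True,
) -> tuple[VoxelTimeSeriesSet, dict]:
    """Run the full cleaning chain on one block; returns (clean series, report)."""
    out = discard_initial(ts, n_discard)
    out, scrubbed = scrub_volumes(out, motion, fd_threshold)
    confounds = extract_confounds(out, motion, gm_mask=gm_mask,
                                  include_global=include_global)
    out = apply_mask(out, gm_mask)
    if filter_before_regression:
        out = bandpass(out, low=low, high=high)
        confounds = ConfoundSet(
            _bandpass_array(confounds.columns.T, out.tr_seconds, low, high).T,
            confounds.names,
        )
        out = nuisance_regress(out, confounds)
    else:
        out = nuisance_regress(out, confounds)
        out = bandpass(out, low=low, high=high)
    report = {
        "n_discarded": n_discard,
        "n_scrubbed": int(len(scrubbed)),
        "n_timepoints": out.n_timepoints,
        "n_voxels": out.n_voxels,
    }
    return out, report
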