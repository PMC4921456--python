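"""Synthetic study generator.

Emulates, at desk scale, the data a voxel-wise rest-vs-task connectivity
study consumes: a labeled toy brain (gray-matter communities, a white-matter
slab, a CSF slab), per-block voxel time series with block-structured
correlations, AR(1) temporal noise, a shared global signal and motion
artifacts, and the 9-subject x 12-block session design (rest, gambling task,
orienting, repeated four times).

The generative model for a gray voxel ``i`` in community ``k`` is a shared-
factor construction that yields an exactly compound-symmetric block
correlation matrix::

    x_i(t) = sqrt(rho_b) u(t) + sqrt(rho_w(k) - rho_b) c_k(t)
             + sqrt(1 - rho_w(k)) e_i(t)

with all factors unit-variance AR(1) processes, so corr(x_i, x_j) equals
``rho_w(k)`` within a community and ``rho_b`` between communities.  The
matrix is positive semi-definite iff ``0 <= rho_b <= min_k rho_w(k) < 1``,
which is validated up front.  A global signal and white measurement noise
are added on top, and motion-flagged volumes receive a step displacement
with a matching jump in the emitted 6-parameter motion trace, giving the
scrubbing and regression stages ground truth to recover.

Rest-like state uses high within- / low between-community coupling; the
task-like state raises between-community coupling and (by default) raises
coupling in the FPN-tagged communities while lowering it in the DMN-tagged
ones, mirroring the direction of task-driven network reconfiguration the
downstream metrics are meant to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .timeseries import VoxelTimeSeriesSet
from .volumes import LabeledVolume, LabelInfo

CONDITIONS = ("rest", "IGT", "orienting")  # fixed block order, repeated 4x
N_SESSIONS = 4
BLOCKS_PER_SUBJECT = len(CONDITIONS) * N_SESSIONS


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    """One gray-matter community: either a voxel count or a sphere (mm)."""

    label: int
    name: str
    count: int | None = None
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float | None = None
    network: str | None = None  # e.g. "DMN", "FPN"

    def __post_init__(self) -> None:
        by_count = self.count is not None
        by_sphere = self.center_mm is not None and self.radius_mm is not None
        if by_count == by_sphere:
            raise ValueError(
                f"community {self.name!r}: give either a voxel count or a sphere"
            )


def _default_affine(shape, voxel_size: float) -> np.ndarray:
    """Isotropic affine centering the grid on the spatial origin."""
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size
    affine[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return affine


def make_toy_atlas(
    shape: tuple[int, int, int],
    community_spec: list[CommunitySpec],
    voxel_size: float = 4.0,
    affine: np.ndarray | None = None,
    wm_label: int = 91,
    csf_label: int = 92,
) -> LabeledVolume:
    """Build a labeled toy volume with gray communities and WM/CSF slabs.

    Count-based communities are carved from the grid interior in raster
    order; sphere communities take every voxel whose center lies within
    ``radius_mm`` of ``center_mm``.  The bottom z-plane becomes a CSF slab
    and the top z-plane a white-matter slab (skipped when ``community_spec``
    is empty, which yields an all-background volume).

    Raises ``ValueError`` naming the offending community if a sphere falls
    outside the grid or regions overlap.
    """
    shape = tuple(int(s) for s in shape)
    if affine is None:
        affine = _default_affine(shape, voxel_size)
    labels = np.zeros(shape, dtype=int)
    table: dict[int, LabelInfo] = {}

    if not community_spec:
        return LabeledVolume(labels=labels, affine=affine, label_table=table)

    if shape[2] < 3:
        raise ValueError("grid too thin for tissue slabs (need >= 3 z-planes)")
    labels[:, :, 0] = csf_label
    labels[:, :, -1] = wm_label
    table[csf_label] = LabelInfo("csf-slab", "csf")
    table[wm_label] = LabelInfo("wm-slab", "white")

    # voxel-center coordinates, used for sphere membership
    idx = np.indices(shape).reshape(3, -1).T
    hom = np.c_[idx, np.ones(len(idx))]
    coords = (np.asarray(affine, float) @ hom.T).T[:, :3]

    for spec in community_spec:
        if spec.label in table:
            raise ValueError(f"community {spec.name!r}: label {spec.label} reused")
        if spec.count is not None:
            free = np.flatnonzero(labels.reshape(-1) == 0)
            if len(free) < spec.count:
                raise ValueError(
                    f"community {spec.name!r} does not fit: "
                    f"{spec.count} voxels requested, {len(free)} free"
                )
            flat = labels.reshape(-1)
            flat[free[: spec.count]] = spec.label
        else:
            d = np.linalg.norm(coords - np.asarray(spec.center_mm), axis=1)
            inside = d <= spec.radius_mm
            if not inside.any():
                raise ValueError(f"community {spec.name!r} lies outside the grid")
            # sphere must be fully contained: its bounding box in mm must fit
            lo = np.asarray(spec.center_mm) - spec.radius_mm
            hi = np.asarray(spec.center_mm) + spec.radius_mm
            cmin, cmax = coords.min(axis=0), coords.max(axis=0)
            if np.any(lo < cmin - 1e-9) or np.any(hi > cmax + 1e-9):
                raise ValueError(
                    f"community {spec.name!r} extends out of bounds"
                )
            taken = labels.reshape(-1)[inside]
            if np.any(taken != 0):
                raise ValueError(f"community {spec.name!r} overlaps another region")
            labels.reshape(-1)[inside] = spec.label
        table[spec.label] = LabelInfo(spec.name, "gray", network=spec.network)

    return LabeledVolume(labels=labels, affine=affine, label_table=table)


def default_study_atlas() -> LabeledVolume:
    """Desk-scale study atlas in 'virtual MNI' millimeter space.

    A (24, 26, 18) grid of 6 mm voxels positioned so the canonical DMN/FPN
    seed coordinates (in mm) fall inside the volume, with one 10 mm-sphere
    gray community per seed plus three generic communities, so ROI masks
    built from the standard coordinate table overlap real nodes.
    """
    from .roimasks import reference_roi_table  # local import: avoid cycle

    shape = (24, 26, 18)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * 6.0
    affine[:3, 3] = (-69.0, -75.0, -22.0)

    specs: list[CommunitySpec] = []
    label = 1
    for roi in reference_roi_table():
        specs.append(
            CommunitySpec(
                label=label,
                name=roi.name,
                center_mm=roi.center,
                radius_mm=10.0,
                network=roi.network,
            )
        )
        label += 1
    for name, center in [
        ("generic-r", (30.0, -10.0, 10.0)),
        ("generic-l", (-30.0, -10.0, 10.0)),
        ("generic-post", (0.0, -15.0, -10.0)),
    ]:
        specs.append(
            CommunitySpec(label=label, name=name, center_mm=center, radius_mm=10.0)
        )
        label += 1
    return make_toy_atlas(shape, specs, affine=affine)


# ---------------------------------------------------------------------------
# time-series simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Knobs of the per-block time-series generator.

    ``rho_within`` / ``rho_between`` are the target block correlations;
    ``community_rho_within`` overrides ``rho_within`` for specific networks
    (keys are network tags such as "DMN"/"FPN").  ``motion_spec`` maps
    volume index -> displacement magnitude in mm for injected motion steps.
    """

    n_timepoints: int = 120
    tr_seconds: float = 2.0
    rho_within: float = 0.60
    rho_between: float = 0.10
    community_rho_within: dict[str, float] = field(default_factory=dict)
    ar1_coef: float = 0.3
    global_signal_sd: float = 0.5
    noise_sd: float = 0.2
    motion_spec: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        rhos = [self.rho_within, *self.community_rho_within.values()]
        if not all(0.0 <= r < 1.0 for r in rhos):
            raise ValueError(f"rho_within values must lie in [0, 1): {rhos}")
        if not 0.0 <= self.rho_between < 1.0:
            raise ValueError(f"rho_between must lie in [0, 1): {self.rho_between}")
        if self.rho_between > min(rhos):
            raise ValueError(
                "implied covariance not PSD: rho_between="
                f"{self.rho_between} exceeds rho_within={min(rhos)}"
            )
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError(f"ar1_coef must lie in (-1, 1): {self.ar1_coef}")
        if self.n_timepoints < 12:
            raise ValueError("n_timepoints too small for the nuisance design")


def rest_params(**overrides) -> SimulationParams:
    """Default rest-like condition: strong within-, weak between-community coupling."""
    p = SimulationParams(
        rho_within=0.60,
        rho_between=0.10,
        community_rho_within={"DMN": 0.68, "FPN": 0.55},
    )
    return replace(p, **overrides)


def task_params(**overrides) -> SimulationParams:
    """Default task-like condition: between-community coupling up, FPN up, DMN down."""
    p = SimulationParams(
        rho_within=0.45,
        rho_between=0.30,
        community_rho_within={"DMN": 0.50, "FPN": 0.62},
    )
    return replace(p, **overrides)


def _ar1(rng: np.random.Generator, n: int, size: int, phi: float) -> np.ndarray:
    """(size, n) stationary AR(1) series with unit marginal variance."""
    out = np.empty((size, n))
    out[:, 0] = rng.standard_normal(size)
    innov_sd = math.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal((size, n - 1)) * innov_sd
    for t in range(1, n):
        out[:, t] = phi * out[:, t - 1] + eps[:, t - 1]
    return out


@dataclass
class SimulatedBlock:
    """One block's series plus the per-volume motion-parameter trace."""

    ts: VoxelTimeSeriesSet
    motion: np.ndarray  # (n_timepoints, 6): 3 translations mm, 3 rotations rad
    state: str


def simulate_timeseries(
    atlas: LabeledVolume,
    state: str,
    params: SimulationParams,
) -> SimulatedBlock:
    """Simulate one block of voxel time series on the given atlas.

    ``state`` is "rest" or "task" (informational; the correlation targets
    come from ``params``).  Returns series for every labeled voxel (gray,
    white, CSF) so nuisance extraction downstream is meaningful.  The same
    seed reproduces the block bit-for-bit.
    """
    params.validate()
    if not atlas.codes_for("gray"):
        raise ValueError("atlas has no gray-matter community")
    rng = np.random.default_rng(params.seed)
    T, phi = params.n_timepoints, params.ar1_coef

    vox = np.argwhere(atlas.labels != 0)
    codes = atlas.labels[tuple(vox.T)]
    n_vox = len(vox)
    data = np.zeros((n_vox, T))

    gray_codes = atlas.codes_for("gray")
    rho_b = params.rho_between
    shared = _ar1(rng, T, 1, phi)[0]  # cross-community factor
    community_factors = {c: _ar1(rng, T, 1, phi)[0] for c in gray_codes}
    tissue_factors = {t: _ar1(rng, T, 1, phi)[0] for t in ("white", "csf")}

    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        info = atlas.label_table[code]
        noise = _ar1(rng, T, len(rows), phi)
        if info.tissue == "gray":
            rho_w = params.community_rho_within.get(
                info.network or "", params.rho_within
            )
            rho_w = max(rho_w, rho_b)  # validated already; guard numerics
            data[rows] = (
                math.sqrt(rho_b) * shared
                + math.sqrt(rho_w - rho_b) * community_factors[code]
                + math.sqrt(1.0 - rho_w) * noise
            )
        else:
            # WM/CSF: moderate within-tissue coherence, no cross-community part
            data[rows] = (
                math.sqrt(0.5) * tissue_factors[info.tissue]
                + math.sqrt(0.5) * noise
            )

    if params.global_signal_sd > 0:
        data += params.global_signal_sd * _ar1(rng, T, 1, phi)[0]
    if params.noise_sd > 0:
        data += params.noise_sd * rng.standard_normal((n_vox, T))

    # motion trace: small jitter plus sustained steps at flagged volumes
    motion = np.zeros((T, 6))
    motion[:, :3] = rng.normal(scale=0.01, size=(T, 3))
    motion[:, 3:] = rng.normal(scale=2e-4, size=(T, 3))
    for t, magnitude in sorted(params.motion_spec.items()):
        if not 0 <= t < T:
            raise ValueError(f"motion_spec volume {t} outside 0..{T - 1}")
        motion[t:, 0] += magnitude  # sustained translation step
        data[:, t] += magnitude  # displacement artifact at the flagged volume

    ts = VoxelTimeSeriesSet(
        data=data,
        voxel_index=vox,
        labels=codes,
        tr_seconds=params.tr_seconds,
        provenance={"state": state, "label_table": dict(atlas.label_table)},
    )
    return SimulatedBlock(ts=ts, motion=motion, state=state)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def make_design_table(n_subjects: int) -> pd.DataFrame:
    """Subject x block bookkeeping: 12 blocks each, rest -> IGT -> orienting x4."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rows = []
    for subject in range(1, n_subjects + 1):
        block = 0
        for session in range(1, N_SESSIONS + 1):
            for condition in CONDITIONS:
                block += 1
                rows.append(
                    {
                        "subject": subject,
                        "block_index": block,
                        "condition": condition,
                        "session": session,
                        "analyze": condition != "orienting",
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(
    n_subjects: int,
    atlas: LabeledVolume | None = None,
    rest: SimulationParams | None = None,
    task: SimulationParams | None = None,
    orienting: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[int, int], SimulatedBlock]]:
    """Generate the full session design and one simulated block per row.

    Returns the design table and a dict keyed by ``(subject, block_index)``.
    Rest blocks use rest-like parameters, IGT blocks task-like; orienting
    blocks (flagged ``analyze=False``) are generated with their own
    (default task-like) parameters so per-block artifacts exist for every
    acquired block even though they are excluded from analysis.
    """
    atlas = atlas if atlas is not None else default_study_atlas()
    base = {
        "rest": rest if rest is not None else rest_params(),
        "IGT": task if task is not None else task_params(),
        "orienting": orienting if orienting is not None else task_params(),
    }
    design = make_design_table(n_subjects)
    ss = np.random.SeedSequence(seed)
    block_seeds = ss.generate_state(len(design))

    blocks: dict[tuple[int, int], SimulatedBlock] = {}
    for row, block_seed in zip(design.itertuples(index=False), block_seeds):
        params = replace(base[row.condition], seed=int(block_seed) % (2**31))
        state = "rest" if row.condition == "rest" else "task"
        blk = simulate_timeseries(atlas, state, params)
        blk.ts.provenance.update(
            subject=int(row.subject),
            block_index=int(row.block_index),
            condition=row.condition,
            session=int(row.session),
        )
        blocks[(int(row.subject), int(row.block_index))] = blk
    return design, blocks
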