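"""Binary voxel-graph construction under the N = K^S density rule.

Each block's cleaned gray-voxel series yields a Pearson correlation matrix.
The correlation cutoff r* is chosen so the network's mean degree K satisfies
K = N^(1/S) for node count N and exponent S (default 2.5): with E =
round(N*K/2) target edges, r* is the E-th largest positive off-diagonal
correlation, and every pair with correlation >= r* becomes an edge.  Fixing
S fixes connection density across blocks and subjects, so degree and
efficiency comparisons are not confounded by density differences.

Negative correlations are never eligible as edges, and ties at r* are all
included (deterministic, order-independent; the realized mean degree is
recorded alongside the target).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .timeseries import VoxelTimeSeriesSet


@dataclass
class ThresholdSpec:
    """Record of one density-thresholding solution."""

    S: float | None
    target_K: float
    r_star: float
    achieved_K: float
    n_nodes: int
    n_edges: int

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "target_K": self.target_K,
            "r_star": self.r_star,
            "achieved_K": self.achieved_K,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
        }


@dataclass
class BinaryNetwork:
    """Symmetric, loop-free 0/1 adjacency over voxel nodes."""

    adjacency: np.ndarray
    node_index: np.ndarray  # (N, 3) voxel grid coordinate per node
    spec: ThresholdSpec | None = None
    provenance: dict = field(default_factory=dict)
    node_labels: np.ndarray | None = None  # atlas code per node

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = A.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def mean_degree(self) -> float:
        return float(self.adjacency.sum(axis=1).mean())

    # -- serialization: edge list + JSON sidecar --------------------------
    def save_edgelist(self, path, sidecar_path=None) -> None:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        with open(path, "w") as fh:
            for i, j in zip(ii, jj):
                fh.write(f"{i} {j}\n")
        if sidecar_path is not None:
            meta = {
                "n_nodes": self.n_nodes,
                "spec": self.spec.to_dict() if self.spec else None,
                "provenance": self.provenance,
                "node_index": self.node_index.tolist(),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh)


def load_edgelist(path, sidecar_path) -> BinaryNetwork:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    n = meta["n_nodes"]
    A = np.zeros((n, n), dtype=np.int8)
    with open(path) as fh:
        for line in fh:
            i, j = map(int, line.split())
            A[i, j] = A[j, i] = 1
    spec = ThresholdSpec(**meta["spec"]) if meta["spec"] else None
    return BinaryNetwork(
        adjacency=A,
        node_index=np.asarray(meta["node_index"], dtype=int),
        spec=spec,
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def correlation_matrix(ts: VoxelTimeSeriesSet) -> np.ndarray:
    """Pearson correlations between every pair of voxel series."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    sd = ts.data.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if len(constant):
        raise ValueError(
            f"constant voxel series at rows {constant.tolist()[:10]}"
            + ("..." if len(constant) > 10 else "")
        )
    corr = np.corrcoef(ts.data)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry against FP noise
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def target_degree(n_nodes: int, S: float) -> float:
    """Mean degree K solving N = K^S, i.e. K = N^(1/S).

    Exact integer solutions (e.g. N = 1024, S = 2.5 -> K = 16) are returned
    exactly: float exponentiation is off by an ulp on such cases, so results
    within 1e-9 of an integer K with round(K)^S == N are snapped.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if S <= 0:
        raise ValueError("S must be positive")
    k = float(n_nodes) ** (1.0 / S)
    k_int = round(k)
    if abs(k - k_int) < 1e-9 and abs(k_int**S - n_nodes) < 1e-6 * n_nodes:
        return float(k_int)
    return k


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def find_threshold(
    corr: np.ndarray,
    S: float | None = 2.5,
    target_K: float | None = None,
) -> ThresholdSpec:
    """Solve the density rule for the correlation cutoff.

    Either ``S`` (target K = N^(1/S)) or an explicit ``target_K`` may be
    given.  r* is the E-th largest positive off-diagonal correlation for
    E = round(N*K/2); the realized mean degree counts ties at r*.
    """
    corr = np.asarray(corr, dtype=float)
    N = corr.shape[0]
    if target_K is None:
        if S is None:
            raise ValueError("give either S or target_K")
        target_K = target_degree(N, S)
    if not 0 < target_K <= N - 1:
        raise ValueError(f"target degree {target_K} outside (0, {N - 1}]")
    E = _round_half_up(N * target_K / 2.0)
    E = max(E, 1)
    upper = corr[np.triu_indices(N, k=1)]
    positive = np.sort(upper[upper > 0])[::-1]
    if len(positive) < E:
        max_K = 2.0 * len(positive) / N
        raise ValueError(
            f"only {len(positive)} positive correlations available for "
            f"{E} requested edges (max attainable mean degree {max_K:.3f})"
        )
    r_star = float(positive[E - 1])
    realized = int(np.count_nonzero(upper >= r_star))
    return ThresholdSpec(
        S=S,
        target_K=float(target_K),
        r_star=r_star,
        achieved_K=2.0 * realized / N,
        n_nodes=N,
        n_edges=realized,
    )


def binarize(
    corr: np.ndarray,
    spec: ThresholdSpec,
    node_index: np.ndarray | None = None,
    provenance: dict | None = None,
    node_labels: np.ndarray | None = None,
) -> BinaryNetwork:
    """Adjacency[i, j] = 1 iff corr[i, j] >= r* and i != j."""
    corr = np.asarray(corr, dtype=float)
    A = (corr >= spec.r_star).astype(np.int8)
    np.fill_diagonal(A, 0)
    if node_index is None:
        node_index = np.zeros((corr.shape[0], 3), dtype=int)
    return BinaryNetwork(
        adjacency=A,
        node_index=np.asarray(node_index, dtype=int),
        spec=spec,
        provenance=dict(provenance or {}),
        node_labels=node_labels,
    )


def build_network(
    ts: VoxelTimeSeriesSet, S: float = 2.5, provenance: dict | None = None
) -> BinaryNetwork:
    """Correlation -> threshold -> binarize for one cleaned block."""
    corr = correlation_matrix(ts)
    spec = find_threshold(corr, S=S)
    prov = dict(ts.provenance)
    prov.pop("label_table", None)
    prov.update(provenance or {})
    return binarize(corr, spec, node_index=ts.voxel_index, provenance=prov,
                    node_labels=ts.labels)


def threshold_sweep(
    corr: np.ndarray,
    S_values: list[float] | None = None,
    target_K_values: list[float] | None = None,
    node_index: np.ndarray | None = None,
    warn: bool = True,
) -> list[BinaryNetwork]:
    """One network per threshold; warns (never fails) on fragmentation.

    Accepts either a list of S exponents or explicit target mean degrees;
    each network's component count is recorded in its provenance.
    """
    import warnings

    from scipy.sparse.csgraph import connected_components

    if (S_values is None) == (target_K_values is None):
        raise ValueError("give exactly one of S_values or target_K_values")
    nets = []
    if S_values is not None:
        specs = [find_threshold(corr, S=s) for s in S_values]
    else:
        specs = [find_threshold(corr, S=None, target_K=k) for k in target_K_values]
    for spec in specs:
        net = binarize(corr, spec, node_index=node_index)
        n_comp, _ = connected_components(net.adjacency, directed=False)
        net.provenance["n_components"] = int(n_comp)
        if warn and n_comp > 1:
            warnings.warn(
                f"network at S={spec.S}, K={spec.target_K:.2f} fragments "
                f"into {n_comp} components",
                stacklevel=2,
            )
        nets.append(net)
    return nets
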