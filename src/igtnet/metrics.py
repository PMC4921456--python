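"""Graph metrics: degree, global efficiency, local efficiency.

Efficiency follows the Latora-Marchiori definition: the mean of inverse
shortest-path lengths over distinct node pairs, with disconnected pairs
contributing 0 (1/inf).  This form is bounded in [0, 1], equals 1 on a
complete graph, and stays finite on fragmented networks, which matters for
high-S threshold sweeps.  Local efficiency of a node is the global
efficiency of the subgraph induced by its neighbors (the node itself
excluded); nodes with fewer than two neighbors have local efficiency 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .netbuild import BinaryNetwork


@dataclass
class MetricMap:
    """Per-node values of one metric, mappable back to voxel space."""

    metric_name: str  # "K", "E_loc", or "E_glob_node"
    values: np.ndarray
    node_index: np.ndarray  # (N, 3) voxel coordinates
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(len(self.values)),
                "x": self.node_index[:, 0],
                "y": self.node_index[:, 1],
                "z": self.node_index[:, 2],
                "value": self.values,
            }
        )

    def to_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Scatter node values into a dense volume (background 0)."""
        vol = np.zeros(shape, dtype=float)
        vol[tuple(self.node_index.T)] = self.values
        return vol


@dataclass
class NetworkSummary:
    """Whole-network metric summary."""

    mean_K: float
    mean_E_loc: float
    E_glob: float
    n_nodes: int
    n_components: int


# ---------------------------------------------------------------------------

def degree_map(net: BinaryNetwork) -> MetricMap:
    """Degree K: row sums of the adjacency matrix."""
    return MetricMap(
        metric_name="K",
        values=net.adjacency.sum(axis=1).astype(float),
        node_index=net.node_index,
        provenance=dict(net.provenance),
    )


def shortest_path_lengths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted shortest-path distances; unreachable pairs are inf."""
    return _distances(net.adjacency)


def _distances(adjacency: np.ndarray) -> np.ndarray:
    A = csr_matrix(np.asarray(adjacency))
    return shortest_path(A, method="D", unweighted=True, directed=False)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    A = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    if A.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _efficiency_from_distances(_distances(A))


def nodal_efficiency_map(net: BinaryNetwork) -> MetricMap:
    """Per-node mean inverse distance to every other node (averages to E_glob)."""
    d = _distances(net.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    values = inv.sum(axis=1) / max(net.n_nodes - 1, 1)
    return MetricMap("E_glob_node", values, net.node_index, dict(net.provenance))


def local_efficiency(net: BinaryNetwork, node: int) -> float:
    """Global efficiency of the node's neighbor-induced subgraph."""
    A = net.adjacency
    if not 0 <= node < net.n_nodes:
        raise ValueError(f"node {node} outside 0..{net.n_nodes - 1}")
    nbrs = np.flatnonzero(A[node])
    if len(nbrs) < 2:
        return 0.0
    sub = A[np.ix_(nbrs, nbrs)]
    return _efficiency_from_distances(_distances(sub))


def local_efficiency_map(net: BinaryNetwork) -> MetricMap:
    values = np.array(
        [local_efficiency(net, i) for i in range(net.n_nodes)], dtype=float
    )
    return MetricMap("E_loc", values, net.node_index, dict(net.provenance))


def network_summary(net: BinaryNetwork) -> NetworkSummary:
    """Whole-network mean degree, mean local efficiency, global efficiency."""
    n_comp, _ = connected_components(csr_matrix(net.adjacency), directed=False)
    return NetworkSummary(
        mean_K=net.mean_degree(),
        mean_E_loc=float(local_efficiency_map(net).values.mean()),
        E_glob=global_efficiency(net) if net.n_nodes >= 2 else 0.0,
        n_nodes=net.n_nodes,
        n_components=int(n_comp),
    )


def roi_mean(metric: MetricMap, mask: np.ndarray, name: str = "mask") -> float:
    """Mean metric value over nodes whose voxels lie inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    inside = mask[tuple(metric.node_index.T)]
    if not inside.any():
        raise ValueError(f"mask {name!r} overlaps no network nodes")
    return float(metric.values[inside].mean())
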