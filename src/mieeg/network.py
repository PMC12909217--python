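"""Sparsified weighted brain graphs and global efficiency.

Connectivity matrices are thresholded proportionally (the strongest fixed
fraction of edges is retained with its weights), optionally summed within a
group and re-thresholded, and summarised by global efficiency

    E_glob = 1 / (N (N - 1)) * sum_{i != j} 1 / d_ij

where ``d_ij`` is the shortest weighted path length between nodes i and j
with edge distance 1/weight (a stronger connection is a shorter hop) and
``1/inf = 0`` for unreachable pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "BrainNetwork",
    "proportional_threshold",
    "aggregate_group",
    "shortest_path_lengths",
    "global_efficiency",
    "build_network",
]


def _check_square_symmetric(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(w, w.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


def proportional_threshold(w: np.ndarray, sparsity: float = 0.3) -> np.ndarray:
    """Keep the strongest ``round(sparsity * K)`` of the K = N(N-1)/2
    undirected edges, zeroing the rest.

    Rounding is half-up (K=45, sparsity 0.3 keeps 14 edges) and ties are
    broken by ascending (row, column) index, so the retained edge count is
    deterministic. ``sparsity=1`` is the identity.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    w = _check_square_symmetric(w)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k_total = len(iu)
    n_keep = int(np.floor(sparsity * k_total + 0.5))  # half-up
    # sort by descending weight, ties by ascending (row, col)
    order = sorted(range(k_total), key=lambda e: (-w[iu[e], ju[e]], iu[e], ju[e]))
    keep = order[:n_keep]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = w[iu[keep], ju[keep]]
    out = out + out.T
    return out


def aggregate_group(
    matrices: list[np.ndarray | ConnectivityMatrix], sparsity: float = 0.3
) -> np.ndarray:
    """Group-level matrix: element-wise sum of per-subject (thresholded)
    matrices, re-thresholded at the same sparsity so the group graph honours
    the configured density."""
    if not matrices:
        raise ValueError("no matrices to aggregate")
    arrays = [m.w if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
              for m in matrices]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("matrices must share shape and node order")
    total = np.sum(arrays, axis=0)
    return proportional_threshold(total, sparsity=sparsity)


def shortest_path_lengths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge distance 1/weight.

    Unreachable pairs get ``inf``; the diagonal is 0.
    """
    w = _check_square_symmetric(w)
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(dist, 0.0)
    d = _csgraph_shortest_path(dist, method="D", directed=False)
    return d


def global_efficiency(w: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    w = _check_square_symmetric(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_path_lengths(w)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


@dataclass
class BrainNetwork:
    """A thresholded weighted graph over the 10 regions with its topology
    summary."""

    nodes: list[str]
    w: np.ndarray
    d: np.ndarray
    e_glob: float
    sparsity: float

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Non-zero undirected edges as (region_i, region_j, weight)."""
        iu, ju = np.triu_indices(len(self.nodes), k=1)
        return [
            (self.nodes[i], self.nodes[j], float(self.w[i, j]))
            for i, j in zip(iu, ju)
            if self.w[i, j] > 0
        ]


def build_network(
    conn: ConnectivityMatrix | np.ndarray,
    nodes: list[str] | None = None,
    sparsity: float = 0.3,
    threshold: bool = True,
) -> BrainNetwork:
    """Threshold a connectivity matrix (optionally skip via ``threshold=False``
    to analyse the raw weighted graph) and compute path lengths and global
    efficiency."""
    if isinstance(conn, ConnectivityMatrix):
        w, nodes = conn.w, list(conn.regions)
    else:
        w = np.asarray(conn, dtype=float)
        nodes = list(nodes) if nodes is not None else [f"n{i}" for i in range(w.shape[0])]
    if threshold:
        w = proportional_threshold(w, sparsity=sparsity)
    d = shortest_path_lengths(w)
    return BrainNetwork(nodes=nodes, w=w, d=d, e_glob=global_efficiency(w), sparsity=sparsity)
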