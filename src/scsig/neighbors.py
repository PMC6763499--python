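"""Weighted K-nearest-neighbor graphs over cells.

Both supported cell-cell similarity inputs — a latent space (Euclidean
distance) and a trajectory (geodesic path distance through the milestone
network) — reduce to the same :class:`NeighborGraph`: for each cell its K
nearest neighbors (default K = ceil(sqrt(N))) with Gaussian distance-decay
weights

    w_ij = exp(-d_ij^2 / sigma_i^2)

where sigma_i is the distance from cell i to its K-th nearest neighbor, so
the kernel decays to e^-1 exactly at the neighborhood boundary.  The graph
is directed: the stored pairs are (i, j in KNN(i)) and no symmetrization is
applied by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .types import LatentSpace, TrajectoryModel

__all__ = [
    "NeighborGraph",
    "knn_from_latent",
    "knn_from_distance_matrix",
    "weights_from_distances",
    "trajectory_distances",
    "knn_from_trajectory",
    "auto_k",
]

# above this size exhaustive pairwise search is replaced by a tree index
_EXACT_LIMIT = 20_000


def auto_k(n_cells: int) -> int:
    """Default neighborhood size: ceil(sqrt(N))."""
    return int(math.ceil(math.sqrt(n_cells)))


@dataclass
class NeighborGraph:
    """Per-cell K nearest neighbors with distances and kernel weights."""

    neighbor_index: np.ndarray  # (N, K) int
    distance: np.ndarray  # (N, K) float, ascending per row
    weight: np.ndarray | None  # (N, K) float in (0, 1], or None before kernel
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.neighbor_index = np.asarray(self.neighbor_index, dtype=int)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.neighbor_index.shape != self.distance.shape:
            raise ValueError("neighbor_index and distance shapes differ")
        n = self.neighbor_index.shape[0]
        if np.any(self.neighbor_index == np.arange(n)[:, None]):
            raise ValueError("a cell may not be its own neighbor")

    @property
    def n_cells(self) -> int:
        return self.neighbor_index.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_index.shape[1]

    @property
    def total_weight(self) -> float:
        """W: sum of all stored pair weights."""
        if self.weight is None:
            raise ValueError("weights not computed; call weights_from_distances")
        return float(self.weight.sum())

    def symmetrized(self) -> scipy.sparse.csr_matrix:
        """(w_ij + w_ji)/2 over the union of directed pairs, as sparse CSR."""
        n = self.n_cells
        rows = np.repeat(np.arange(n), self.k)
        w = scipy.sparse.csr_matrix(
            (self.weight.ravel(), (rows, self.neighbor_index.ravel())), shape=(n, n)
        )
        return (w + w.T) * 0.5

    def to_edge_frame(self):
        import pandas as pd

        n = self.n_cells
        return pd.DataFrame(
            {
                "cell": np.repeat(np.arange(n), self.k),
                "neighbor": self.neighbor_index.ravel(),
                "distance": self.distance.ravel(),
                "weight": self.weight.ravel() if self.weight is not None else np.nan,
            }
        )


def _knn_rows_from_dense(dist_block: np.ndarray, row_offset: int, k: int):
    """Stable per-row top-K on a dense distance block (ties -> lower index)."""
    block = dist_block.copy()
    for r in range(block.shape[0]):
        block[r, row_offset + r] = np.inf  # exclude self
    order = np.argsort(block, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(block, order, axis=1)
    return order, d


def knn_from_distance_matrix(
    dist: np.ndarray, cell_ids: list[str], k: int | None = None
) -> NeighborGraph:
    """Exact KNN from a full pairwise distance matrix."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if k is None:
        k = auto_k(n)
    if k >= n:
        raise ValueError(f"K={k} must be smaller than the number of cells ({n})")
    idx, d = _knn_rows_from_dense(dist, 0, k)
    graph = NeighborGraph(idx, d, None, list(cell_ids))
    return weights_from_distances(graph)


def knn_from_latent(latent: LatentSpace, k: int | None = None) -> NeighborGraph:
    """Euclidean KNN in a latent space; exact for moderate N, tree index above.

    Ties in distance are broken by cell index so results are deterministic.
    """
    n = latent.n_cells
    if k is None:
        k = auto_k(n)
    if k >= n:
        raise ValueError(f"K={k} must be smaller than the number of cells ({n})")
    coords = latent.coords
    if n <= _EXACT_LIMIT:
        idx = np.empty((n, k), dtype=int)
        d = np.empty((n, k), dtype=float)
        chunk = max(1, int(2e7 // max(n, 1)))
        sq = (coords**2).sum(axis=1)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            block = (
                sq[start:stop, None] - 2.0 * coords[start:stop] @ coords.T + sq[None, :]
            )
            np.maximum(block, 0.0, out=block)
            np.sqrt(block, out=block)
            idx[start:stop], d[start:stop] = _knn_rows_from_dense(block, start, k)
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        d_all, idx_all = nn.kneighbors(coords)
        # drop self (always first at distance 0 among ties)
        mask_self = idx_all == np.arange(n)[:, None]
        idx = np.empty((n, k), dtype=int)
        d = np.empty((n, k), dtype=float)
        for i in range(n):
            keep = ~mask_self[i]
            idx[i] = idx_all[i, keep][:k]
            d[i] = d_all[i, keep][:k]
    graph = NeighborGraph(idx, d, None, list(latent.cell_ids))
    return weights_from_distances(graph)


def weights_from_distances(
    graph: NeighborGraph, bandwidth: str = "squared"
) -> NeighborGraph:
    """Apply the Gaussian kernel to a graph's neighbor distances.

    ``bandwidth="squared"`` (default) takes sigma_i = d_iK so the kernel
    argument d^2/sigma^2 is dimensionless and equals 1 at the K-th
    neighbor; ``"literal"`` instead plugs sigma_i^2 = d_iK into the
    denominator unsquared.  Rows whose K-th neighbor sits at distance 0
    (duplicate points) get uniform weight 1.
    """
    if bandwidth not in ("squared", "literal"):
        raise ValueError("bandwidth must be 'squared' or 'literal'")
    d = graph.distance
    sigma = d[:, -1]
    degenerate = sigma <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cells have duplicate-point neighborhoods; "
            "using uniform weights for those rows"
        )
    denom = np.where(degenerate, 1.0, sigma**2 if bandwidth == "squared" else sigma)
    w = np.exp(-(d**2) / denom[:, None])
    w[degenerate] = 1.0
    return NeighborGraph(graph.neighbor_index, d, w, graph.cell_ids)


def trajectory_distances(traj: TrajectoryModel) -> np.ndarray:
    """Pairwise geodesic distances between cells placed on a milestone network.

    A cell on edge (a, b) at progress p sits at distance p*len from a and
    (1-p)*len from b.  The distance between two cells is the shortest path
    through the network between their positions; cells sharing an edge may
    also connect directly along it.
    """
    ms_idx = {m: i for i, m in enumerate(traj.milestones)}
    n_ms = len(traj.milestones)
    rows, cols, vals = [], [], []
    for a, b, ln in traj.edges:
        rows.append(ms_idx[a]), cols.append(ms_idx[b]), vals.append(ln)
    adj = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n_ms, n_ms))
    n_comp, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [
            [m for m, l in zip(traj.milestones, labels) if l == c]
            for c in range(n_comp)
        ]
        raise ValueError(f"milestone network is disconnected: components {comps}")
    dist_ms = scipy.sparse.csgraph.shortest_path(adj, directed=False)

    n = traj.n_cells
    a_idx = np.array([ms_idx[e[0]] for e in traj.cell_edges])
    b_idx = np.array([ms_idx[e[1]] for e in traj.cell_edges])
    lengths = {}
    for a, b, ln in traj.edges:
        lengths[(a, b)] = ln
        lengths[(b, a)] = ln
    edge_len = np.array([lengths[tuple(e)] for e in traj.cell_edges])
    d_a = traj.progress * edge_len  # distance to "from" milestone
    d_b = (1.0 - traj.progress) * edge_len

    # cell -> milestone geodesics, then cell -> cell via the target's endpoints
    cm = np.minimum(d_a[:, None] + dist_ms[a_idx], d_b[:, None] + dist_ms[b_idx])
    dist = np.minimum(cm[:, a_idx] + d_a[None, :], cm[:, b_idx] + d_b[None, :])

    # cells sharing an edge (either orientation) can connect directly
    key = np.minimum(a_idx, b_idx) * n_ms + np.maximum(a_idx, b_idx)
    same = key[:, None] == key[None, :]
    pos_a = np.where(a_idx <= b_idx, d_a, d_b)  # offset from canonical endpoint
    direct = np.abs(pos_a[:, None] - pos_a[None, :])
    dist = np.where(same, np.minimum(dist, direct), dist)
    np.fill_diagonal(dist, 0.0)
    return dist


def knn_from_trajectory(traj: TrajectoryModel, k: int | None = None) -> NeighborGraph:
    """KNN graph over tree-based geodesic distances along a trajectory."""
    dist = trajectory_distances(traj)
    return knn_from_distance_matrix(dist, traj.cell_ids, k)
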