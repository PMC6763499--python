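"""Micro-pooling: merge similar cells into small pools before analysis.

Very large datasets are reduced by partitioning cells into transcriptionally
homogeneous micro-clusters of at most ``pool_size`` cells and replacing each
cluster by its average expression profile.  The partition is built from the
expression data itself: a detection filter (genes seen in >= 10% of cells)
and a Fano-factor variable-gene filter, a 20-dimensional PCA, a
K = ceil(sqrt(N)) nearest-neighbor graph, Louvain community detection, and
finally K-means splitting of any community larger than the pool-size bound.

Pool quality can be audited with :func:`coherence_ratios`: for any per-cell
feature (e.g. a protein measured alongside the transcriptome) the ratio
r = sigma_within_pool / sigma_population should sit well below 1 when pools
group biologically coherent cells, and near 1 for arbitrary pools.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd

from .neighbors import NeighborGraph, knn_from_latent
from .types import ExpressionMatrix, LatentSpace

__all__ = [
    "PoolAssignment",
    "filter_genes",
    "micropool",
    "coherence_ratios",
]


@dataclass
class PoolAssignment:
    """Partition of cells into micro-pools."""

    cell_ids: list[str]
    pool_labels: np.ndarray  # (N,) int pool index per cell
    pool_size_limit: int

    def __post_init__(self) -> None:
        self.pool_labels = np.asarray(self.pool_labels, dtype=int)
        if len(self.cell_ids) != len(self.pool_labels):
            raise ValueError("pool labels must align with cell ids")

    @property
    def n_pools(self) -> int:
        return int(self.pool_labels.max()) + 1

    @property
    def pool_sizes(self) -> np.ndarray:
        return np.bincount(self.pool_labels, minlength=self.n_pools)

    @property
    def cell_to_pool(self) -> dict[str, int]:
        return dict(zip(self.cell_ids, self.pool_labels.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "pool": self.pool_labels})


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def filter_genes(
    expr: ExpressionMatrix,
    detection_fraction: float = 0.1,
    n_bins: int = 30,
    mad_factor: float = 2.0,
) -> ExpressionMatrix:
    """Detection filter then Fano-factor variable-gene filter.

    Genes must be nonzero in at least ``detection_fraction`` of cells.
    Surviving genes are binned into ``n_bins`` mean-expression quantile
    bins; within each bin genes whose Fano factor (variance / mean)
    exceeds the bin median plus ``mad_factor`` MADs are kept.  If the
    variable-gene step degenerates (too few genes, or no within-bin
    spread) it falls back to the detection filter alone.
    """
    detected = (expr.values > 0).mean(axis=1) >= detection_fraction
    if detected.sum() < 2:
        raise ValueError("fewer than 2 genes pass the detection filter")
    kept = expr.subset_genes(np.where(detected)[0])

    mean = kept.values.mean(axis=1)
    var = kept.values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / mean, 0.0)
    if np.allclose(fano, fano[0]):
        warnings.warn("degenerate Fano distribution; keeping detection filter only")
        return kept
    n_bins_eff = min(n_bins, len(mean))
    # quantile bins on mean expression; rank-based so ties spread evenly
    order = np.argsort(np.argsort(mean, kind="stable"), kind="stable")
    bins = (order * n_bins_eff) // len(mean)
    keep_var = np.zeros(len(mean), dtype=bool)
    for b in range(n_bins_eff):
        in_bin = bins == b
        if not in_bin.any():
            continue
        f = fano[in_bin]
        thresh = np.median(f) + mad_factor * _mad(f)
        keep_var[in_bin] = f > thresh
    if keep_var.sum() < 2:
        warnings.warn("variable-gene filter kept <2 genes; using detection filter only")
        return kept
    return kept.subset_genes(np.where(keep_var)[0])


def _pca_embedding(expr: ExpressionMatrix, n_components: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    x = expr.values.T  # cells x genes
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    return PCA(n_components=n_comp, random_state=seed).fit_transform(x)


def _louvain_labels(graph: NeighborGraph, seed: int) -> np.ndarray:
    n = graph.n_cells
    edges = {}
    for i in range(n):
        for j, w in zip(graph.neighbor_index[i], graph.weight[i]):
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges[(a, b)] = edges.get((a, b), 0.0) + float(w)
    g = igraph.Graph(n=n, edges=list(edges.keys()))
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=list(edges.values()))
    igraph.set_random_number_generator(random)
    return np.asarray(part.membership, dtype=int)


def _split_oversized(
    coords: np.ndarray, labels: np.ndarray, limit: int, seed: int
) -> np.ndarray:
    """K-means split of clusters above the size bound, repeated until it holds."""
    from sklearn.cluster import KMeans

    labels = labels.copy()
    next_label = labels.max() + 1
    stack = [l for l in np.unique(labels)]
    while stack:
        l = stack.pop()
        members = np.where(labels == l)[0]
        size = len(members)
        if size <= limit:
            continue
        k = int(math.ceil(size / limit))
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords[members])
        for sub in range(k):
            sub_members = members[km.labels_ == sub]
            if sub == 0:
                labels[sub_members] = l
                if len(sub_members) > limit:
                    stack.append(l)
            else:
                labels[sub_members] = next_label
                if len(sub_members) > limit:
                    stack.append(next_label)
                next_label += 1
    return labels


def micropool(
    expr: ExpressionMatrix,
    pool_size: int = 20,
    seed: int = 0,
    n_pca: int = 20,
) -> tuple[PoolAssignment, ExpressionMatrix]:
    """Partition cells into pools of at most ``pool_size`` and average them.

    Returns the assignment and the pooled matrix (all genes of the input,
    one column per pool, each the mean over its member cells).  When
    ``pool_size >= N`` the result is a single pool holding every cell.
    """
    n = expr.n_cells
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if pool_size >= n:
        labels = np.zeros(n, dtype=int)
    else:
        filtered = filter_genes(expr)
        coords = _pca_embedding(filtered, n_pca, seed)
        graph = knn_from_latent(LatentSpace(coords, expr.cell_ids))
        labels = _louvain_labels(graph, seed)
        if np.bincount(labels).max() <= 1:
            warnings.warn("Louvain produced only singletons; using plain K-means")
            from sklearn.cluster import KMeans

            k = int(math.ceil(n / pool_size))
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
        labels = _split_oversized(coords, labels, pool_size, seed)
    # relabel pools compactly in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    assignment = PoolAssignment(list(expr.cell_ids), labels, pool_size)
    n_pools = assignment.n_pools
    pooled = np.zeros((expr.n_genes, n_pools))
    for z in range(n_pools):
        pooled[:, z] = expr.values[:, labels == z].mean(axis=1)
    pooled_expr = ExpressionMatrix(
        pooled, list(expr.gene_ids), [f"pool_{z}" for z in range(n_pools)]
    )
    return assignment, pooled_expr


def coherence_ratios(
    features: pd.DataFrame, assignment: PoolAssignment
) -> pd.DataFrame:
    """Within-pool vs population standard-deviation ratio per feature.

    ``features`` is features x cells (columns aligned to the assignment's
    cells).  For feature p and pool i, r_pi = sigma_pi / sigma_p with
    population (1/N) variances; size-1 pools get r = 0 by convention and
    are flagged in the ``singleton`` column.
    """
    values = features.to_numpy(dtype=float)
    if values.shape[1] != len(assignment.cell_ids):
        raise ValueError("feature columns must align with assignment cells")
    sigma_p = values.std(axis=1)
    if np.any(sigma_p == 0):
        bad = [str(f) for f, s in zip(features.index, sigma_p) if s == 0]
        raise ValueError(f"features with zero population variance: {bad[:5]}")
    rows = []
    for z in range(assignment.n_pools):
        members = assignment.pool_labels == z
        size = int(members.sum())
        if size == 1:
            for f in features.index:
                rows.append((str(f), z, 0.0, True))
            continue
        sigma_pi = values[:, members].std(axis=1)
        for f, s_pi, s_p in zip(features.index, sigma_pi, sigma_p):
            rows.append((str(f), z, float(s_pi / s_p), False))
    return pd.DataFrame(rows, columns=["feature", "pool", "ratio", "singleton"])
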