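"""Rank-based local autocorrelation of signature scores on a cell graph.

The statistic is Geary's C evaluated on the per-signature ranks of the
corrected scores,

    C = (N - 1) * sum_ij w_ij (x_i - x_j)^2 / (2 W sum_i (x_i - xbar)^2),

with the sum running over the directed stored pairs (i, j in KNN(i)) and
W the total stored weight.  Results are reported as C' = 1 - C, so 0 means
no local autocorrelation and 1 maximal smoothness on the graph.

Significance comes from an empirical null of random signatures drawn from
the matrix's gene universe.  Input signatures are clustered (k-means, k=5)
by log10 size and sign balance; each cluster center spawns a group of
random signatures matched in size and balance, scored through the *same*
correction and ranking path, and the one-sided empirical p-value for a
signature is (x + 1) / (n_bg + 1) with x the number of null C' values at
or above the observed one.  Benjamini-Hochberg correction is applied
across the tested family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .neighbors import NeighborGraph
from .scoring import SignatureScoreMatrix, score_all
from .types import ExpressionMatrix, GeneSignature, MetaData

__all__ = [
    "geary_c",
    "geary_c_batch",
    "rank_rows",
    "signature_autocorrelation",
    "BackgroundGroup",
    "build_backgrounds",
    "compute_background_nulls",
    "empirical_pvalues",
    "analyze_signatures",
    "metadata_numeric_autocorrelation",
]

_DEFAULT_N_BACKGROUND = 500
_N_GROUPS = 5


def geary_c(values: np.ndarray, graph: NeighborGraph) -> float:
    """Geary's C of one value vector on the weighted KNN graph.

    Returns NaN when the values have zero variance (the statistic is then
    undefined).
    """
    values = np.asarray(values, dtype=float)
    n = graph.n_cells
    if values.shape != (n,):
        raise ValueError("values must align with graph cells")
    if n < 3:
        raise ValueError("need at least 3 cells")
    denom_var = ((values - values.mean()) ** 2).sum()
    if denom_var == 0:
        return float("nan")
    diff2 = (values[:, None] - values[graph.neighbor_index]) ** 2
    num = (graph.weight * diff2).sum()
    return float((n - 1) * num / (2.0 * graph.total_weight * denom_var))


def geary_c_batch(
    matrix: np.ndarray, graph: NeighborGraph, chunk: int = 64
) -> np.ndarray:
    """Geary's C for each row of a (vectors x cells) matrix.

    Chunked so the (chunk, N, K) gather stays within memory on large
    graphs; constant rows yield NaN.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = graph.n_cells
    if matrix.shape[1] != n:
        raise ValueError("matrix columns must align with graph cells")
    out = np.empty(matrix.shape[0])
    w = graph.weight
    two_w = 2.0 * graph.total_weight
    for start in range(0, matrix.shape[0], chunk):
        block = matrix[start : start + chunk]
        centered = block - block.mean(axis=1, keepdims=True)
        denom = (centered**2).sum(axis=1)
        diff2 = (block[:, :, None] - block[:, graph.neighbor_index]) ** 2
        num = (diff2 * w[None, :, :]).sum(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            out[start : start + chunk] = np.where(
                denom > 0, (n - 1) * num / (two_w * denom), np.nan
            )
    return out


def rank_rows(matrix: np.ndarray) -> np.ndarray:
    """Average-tie ranks within each row."""
    return scipy.stats.rankdata(np.atleast_2d(matrix), axis=1)


def signature_autocorrelation(
    scores: SignatureScoreMatrix, graph: NeighborGraph
) -> pd.DataFrame:
    """Per-signature C' on within-signature rank-transformed scores."""
    c = geary_c_batch(rank_rows(scores.scores), graph)
    c_prime = 1.0 - c
    df = pd.DataFrame({"signature": scores.signature_names, "c_prime": c_prime})
    n_const = int(np.isnan(c_prime).sum())
    if n_const:
        warnings.warn(f"{n_const} constant score vectors: C' undefined (NaN)")
    return df


@dataclass
class BackgroundGroup:
    """Random signatures matched to one (size, balance) cluster center."""

    center_log10_size: float
    center_balance: float
    size: int
    n_pos: int
    signatures: list[GeneSignature]
    c_prime_null: np.ndarray | None = field(default=None)


def build_backgrounds(
    sigs: list[GeneSignature],
    gene_universe: list[str],
    n_per_group: int = _DEFAULT_N_BACKGROUND,
    seed: int = 0,
    n_groups: int = _N_GROUPS,
) -> tuple[list[BackgroundGroup], np.ndarray]:
    """Cluster signatures by (log10 size, balance) and draw matched nulls.

    Returns the background groups and, per input signature, the index of
    its assigned group.  With fewer signatures than ``n_groups`` the group
    count shrinks to the number of signatures.
    """
    from sklearn.cluster import KMeans

    if not sigs:
        raise ValueError("no signatures to build backgrounds for")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    feats = np.array([[np.log10(s.size), s.balance] for s in sigs])
    k = min(n_groups, len(sigs))
    if k < n_groups:
        warnings.warn(f"only {len(sigs)} signatures; using {k} background groups")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
    assignment = km.labels_.astype(int)
    groups: list[BackgroundGroup] = []
    for center in km.cluster_centers_:
        log_size, balance = float(center[0]), float(np.clip(center[1], 0.0, 1.0))
        size = int(round(10**log_size))
        size = max(1, size)
        if size > len(universe):
            warnings.warn(
                f"background size {size} exceeds gene universe ({len(universe)}); capped"
            )
            size = len(universe)
        n_pos = int(np.ceil(balance * size))
        n_pos = min(max(n_pos, 0), size)
        members = []
        for b in range(n_per_group):
            chosen = rng.choice(len(universe), size=size, replace=False)
            genes = [universe[i] for i in chosen]
            members.append(
                GeneSignature(
                    f"bg_{len(groups)}_{b}",
                    frozenset(genes[:n_pos]),
                    frozenset(genes[n_pos:]),
                )
            )
        groups.append(BackgroundGroup(log_size, balance, size, n_pos, members))
    return groups, assignment


def compute_background_nulls(
    expr: ExpressionMatrix, graph: NeighborGraph, groups: list[BackgroundGroup]
) -> None:
    """Score each group's random signatures through the full pipeline.

    Fills ``c_prime_null`` in place: corrected scores -> ranks -> C', the
    identical path used for real signatures, so the null reflects every
    stage and not just the statistic.
    """
    for group in groups:
        scored = score_all(expr, group.signatures)
        c = geary_c_batch(rank_rows(scored.scores), graph)
        group.c_prime_null = 1.0 - c[~np.isnan(c)]
        if group.c_prime_null.size == 0:
            raise ValueError("background group produced no usable null values")


def empirical_pvalues(
    observed: pd.DataFrame,
    groups: list[BackgroundGroup],
    assignment: np.ndarray,
) -> pd.DataFrame:
    """One-sided empirical p-values against the grouped nulls, plus BH FDR.

    ``observed`` needs columns ``signature`` and ``c_prime``; rows align
    with ``assignment``.
    """
    p = np.full(len(observed), np.nan)
    for i, (c_prime, g) in enumerate(zip(observed["c_prime"], assignment)):
        null = groups[g].c_prime_null
        if null is None:
            raise ValueError("background nulls not computed")
        if np.isnan(c_prime):
            continue
        x = int((null >= c_prime).sum())
        p[i] = (x + 1) / (null.size + 1)
    out = observed.copy()
    out["p_value"] = p
    out["fdr"] = bh_fdr(p)
    out["background_group"] = assignment
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def analyze_signatures(
    expr: ExpressionMatrix,
    sigs: list[GeneSignature],
    graph: NeighborGraph,
    n_background: int = _DEFAULT_N_BACKGROUND,
    seed: int = 0,
    scores: SignatureScoreMatrix | None = None,
) -> pd.DataFrame:
    """Score signatures, compute C', and test against random backgrounds.

    Convenience wrapper chaining the full label-free analysis; returns a
    frame with columns signature, c_prime, p_value, fdr, background_group.
    """
    if scores is None:
        scores = score_all(expr, sigs)
    observed = signature_autocorrelation(scores, graph)
    kept = [s for s in sigs if s.name in set(scores.signature_names)]
    groups, assignment = build_backgrounds(
        kept, list(expr.gene_ids), n_per_group=n_background, seed=seed
    )
    compute_background_nulls(expr, graph, groups)
    return empirical_pvalues(observed, groups, assignment)


def metadata_numeric_autocorrelation(
    meta: MetaData,
    graph: NeighborGraph,
    n_perm: int = 1000,
    seed: int = 0,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Permutation test of numeric meta-data autocorrelation on the graph.

    Each numeric column (e.g. UMI count, cell detection ratio) is rank
    transformed and its C' compared against ``n_perm`` random permutations
    of the column; p = (x + 1)/(n_perm + 1).  ``stratify_by`` names a
    categorical column (e.g. donor) within whose levels the permutation is
    confined, which removes between-group signal and isolates within-group
    structure.  BH correction across the numeric columns.
    """
    if meta.numeric.empty:
        return pd.DataFrame(columns=["variable", "c_prime", "p_value", "fdr"])
    rng = np.random.default_rng(seed)
    strata = None
    if stratify_by is not None:
        if stratify_by not in meta.categorical.columns:
            raise KeyError(f"no categorical column {stratify_by!r}")
        labels = meta.categorical[stratify_by].to_numpy()
        strata = [np.where(labels == l)[0] for l in pd.unique(labels)]
    rows = []
    for col in meta.numeric.columns:
        x = meta.numeric[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append((col, np.nan, np.nan))
            warnings.warn(f"constant numeric column {col!r}: autocorrelation undefined")
            continue
        obs = 1.0 - geary_c(scipy.stats.rankdata(x), graph)
        perm_mat = np.empty((n_perm, len(x)))
        for b in range(n_perm):
            xp = x.copy()
            if strata is None:
                xp = rng.permutation(x)
            else:
                for idx in strata:
                    xp[idx] = x[rng.permutation(idx)]
            perm_mat[b] = scipy.stats.rankdata(xp)
        null = 1.0 - geary_c_batch(perm_mat, graph)
        x_count = int((null >= obs).sum())
        rows.append((col, obs, (x_count + 1) / (n_perm + 1)))
    df = pd.DataFrame(rows, columns=["variable", "c_prime", "p_value"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df
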