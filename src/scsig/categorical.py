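"""Local-structure test for discrete meta-data (batch, donor, cluster).

Geary's C needs numeric values, so categorical variables are tested
differently: for every cell the weighted distribution of its neighbors'
labels is computed (local proportions), these are aggregated into a square
L x L contingency table whose row l sums the local distributions seen
around cells of level l, and the table is evaluated with a Pearson
chi-squared test.  The effect size is Cramér's V = sqrt(chi2 / (T (L-1)))
in [0, 1], which is the primary ranking because with many cells even a
negligible local structure reaches significance.

The table entries are fractional (kernel-weighted) counts used as-is; the
chi-squared sampling assumptions for integer counts therefore hold only
approximately, which is one more reason V, not p, drives interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .autocorr import bh_fdr
from .neighbors import NeighborGraph

__all__ = [
    "CategoricalAutocorrResult",
    "local_proportions",
    "contingency_from_proportions",
    "categorical_test",
    "metadata_categorical_autocorrelation",
]


@dataclass
class CategoricalAutocorrResult:
    variable: str
    cramers_v: float
    chi2: float
    dof: int
    p_value: float
    levels: list[str]


def _levels_of(labels: np.ndarray) -> list[str]:
    return sorted(pd.unique(labels).tolist())


def local_proportions(
    labels: np.ndarray, graph: NeighborGraph, levels: list[str] | None = None
) -> pd.DataFrame:
    """Weighted neighbor-label counts per cell: chat_im = sum_j w_ij I_m(c_j).

    Rows are cells, columns the label levels; row sums equal each cell's
    total outgoing weight (the counts are not normalized).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_cells:
        raise ValueError("labels must align with graph cells")
    missing = pd.isna(labels)
    if missing.any():
        ids = [graph.cell_ids[i] for i in np.where(missing)[0][:5]]
        raise ValueError(f"unlabeled cells: {ids}")
    if levels is None:
        levels = _levels_of(labels)
    level_idx = {l: i for i, l in enumerate(levels)}
    unknown = set(labels) - set(levels)
    if unknown:
        raise ValueError(f"labels outside declared levels: {sorted(unknown)[:5]}")
    codes = np.array([level_idx[l] for l in labels])
    n, k = graph.n_cells, graph.k
    neigh_codes = codes[graph.neighbor_index]  # (N, K)
    props = np.zeros((n, len(levels)))
    for m in range(len(levels)):
        props[:, m] = (graph.weight * (neigh_codes == m)).sum(axis=1)
    return pd.DataFrame(props, index=graph.cell_ids, columns=levels)


def contingency_from_proportions(
    props: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Aggregate local label distributions by the center cell's own level.

    X_lm = sum over cells i of level l of chat_im — row l is the summed
    neighborhood composition around cells labeled l.
    """
    labels = np.asarray(labels)
    levels = list(props.columns)
    extra = set(labels) - set(levels)
    if extra:
        raise ValueError(f"labels missing from proportion columns: {sorted(extra)[:5]}")
    table = np.zeros((len(levels), len(levels)))
    values = props.to_numpy()
    for l, level in enumerate(levels):
        table[l] = values[labels == level].sum(axis=0)
    return pd.DataFrame(table, index=levels, columns=levels)


def categorical_test(
    table: pd.DataFrame, variable: str = ""
) -> CategoricalAutocorrResult:
    """Pearson chi-squared test of the contingency table plus Cramér's V.

    Levels with empty row and column sums are dropped with a warning; a
    1x1 table (single level) is an error.  No continuity correction is
    applied (the fractional-count construction would make it meaningless).
    """
    x = table.to_numpy(dtype=float)
    if x.shape[0] != x.shape[1]:
        raise ValueError("contingency table must be square")
    keep = (x.sum(axis=0) > 0) & (x.sum(axis=1) > 0)
    if not keep.all():
        dropped = [l for l, k in zip(table.index, keep) if not k]
        warnings.warn(f"dropping empty levels {dropped}")
        x = x[np.ix_(keep, keep)]
    levels = [str(l) for l, k in zip(table.index, keep) if k]
    n_levels = x.shape[0]
    if n_levels < 2:
        raise ValueError("need at least 2 non-empty levels")
    total = x.sum()
    expected = np.outer(x.sum(axis=1), x.sum(axis=0)) / total
    chi2 = float(((x - expected) ** 2 / expected).sum())
    dof = (n_levels - 1) ** 2
    p = float(scipy.stats.chi2.sf(chi2, dof))
    v = float(np.sqrt(chi2 / (total * (n_levels - 1))))
    return CategoricalAutocorrResult(variable, v, chi2, dof, p, levels)


def metadata_categorical_autocorrelation(
    categorical: pd.DataFrame, graph: NeighborGraph
) -> pd.DataFrame:
    """Run the full local-proportion test for each categorical column.

    Returns a frame with variable, cramers_v, chi2, dof, p_value, fdr
    (BH across the categorical family).  Single-level columns are skipped
    with a warning.
    """
    rows = []
    for col in categorical.columns:
        labels = categorical[col].to_numpy()
        if len(pd.unique(labels)) < 2:
            warnings.warn(f"categorical column {col!r} has one level; skipped")
            continue
        props = local_proportions(labels, graph)
        table = contingency_from_proportions(props, labels)
        r = categorical_test(table, variable=col)
        rows.append((r.variable, r.cramers_v, r.chi2, r.dof, r.p_value))
    df = pd.DataFrame(rows, columns=["variable", "cramers_v", "chi2", "dof", "p_value"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else np.array([])
    return df
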