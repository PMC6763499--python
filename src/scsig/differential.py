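"""Label-based differential signature analysis (1-vs-all).

For every categorical stratification, each signature's scores in one level
are compared against all remaining cells with a two-sided Wilcoxon
rank-sum test; the effect size is the Mann-Whitney U statistic rescaled to
the area under the ROC curve, AUROC = U / (n1 * n2), where 0.5 means no
separation and 1.0 perfect up-regulation in the group.  BH correction is
applied across all (signature, level) pairs of one stratification.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .autocorr import bh_fdr
from .scoring import SignatureScoreMatrix
from .types import ExpressionMatrix

__all__ = ["one_vs_all", "differential_genes", "auroc"]


def auroc(in_group: np.ndarray, out_group: np.ndarray) -> float:
    """AUROC of in-group vs out-group values: (wins + ties/2) / (n1*n2)."""
    u = scipy.stats.mannwhitneyu(in_group, out_group, alternative="two-sided")
    return float(u.statistic / (len(in_group) * len(out_group)))


def _test_matrix(values: np.ndarray, names: list[str], labels: np.ndarray) -> pd.DataFrame:
    """Wilcoxon 1-vs-all per (row, level) on a (features x cells) matrix."""
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[1]:
        raise ValueError("labels must align with cells")
    levels = pd.unique(labels)
    rows = []
    for level in levels:
        mask = labels == level
        n1, n2 = int(mask.sum()), int((~mask).sum())
        if n1 < 2 or n2 < 1:
            warnings.warn(f"level {level!r} has too few cells; skipped")
            continue
        for name, x in zip(names, values):
            res = scipy.stats.mannwhitneyu(x[mask], x[~mask], alternative="two-sided")
            a = float(res.statistic / (n1 * n2))
            rows.append((name, level, a, float(res.pvalue), "up" if a >= 0.5 else "down"))
    df = pd.DataFrame(rows, columns=["signature", "group", "auroc", "p_value", "direction"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else np.array([])
    return df


def one_vs_all(scores: SignatureScoreMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Differential signature test for every (signature, level) pair."""
    return _test_matrix(scores.scores, scores.signature_names, labels)


def differential_genes(
    expr: ExpressionMatrix, labels: np.ndarray, genes: list[str]
) -> pd.DataFrame:
    """The same 1-vs-all machinery applied to single-gene expression rows.

    Unknown genes are reported and skipped; BH within the requested gene
    family.
    """
    index = expr.gene_index()
    found, rows = [], []
    missing = []
    for g in genes:
        if g.upper() in index:
            found.append(g)
            rows.append(index[g.upper()])
        else:
            missing.append(g)
    if missing:
        warnings.warn(f"genes not in matrix, skipped: {missing[:10]}")
    if not found:
        raise ValueError("none of the requested genes are in the matrix")
    df = _test_matrix(expr.values[rows], found, labels)
    return df.rename(columns={"signature": "gene"})
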