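"""Per-cell signature scores with analytic random-signature correction.

For a signature with positive set ``G_pos`` (n genes used) and negative set
``G_neg`` (m genes used), the raw score of cell j is

    s_j = (sum_{g in G_pos} e_gj - sum_{g in G_neg} e_gj) / (n + m)

on normalized log-scale expression ``e``.  Raw scores correlate with
per-cell technical covariates (library size, detection rate), so each is
z-normalized against the analytic moments of a *random* signature of the
same size and sign balance drawn from the matrix's gene universe:

    E[R_j]   = ((n - m) / (n + m)) * mean_j
    var(R_j) = var_j / (n + m)
    s'_j     = (s_j - E[R_j]) / sqrt(var(R_j))

where ``mean_j`` and ``var_j`` are the mean and population variance of cell
j's expression over *all* genes in the (filtered) matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .types import ExpressionMatrix, GeneSignature

__all__ = [
    "SignatureScoreMatrix",
    "match_genes",
    "raw_score",
    "corrected_score",
    "score_all",
    "gene_signature_covariance",
    "cell_moments",
]


@dataclass
class SignatureScoreMatrix:
    """Signatures x cells score matrix plus bookkeeping.

    ``gene_counts`` records (n_pos_used, n_neg_used) per signature;
    ``dropped`` maps signature name -> reason for signatures that could
    not be scored (e.g. no genes found in the matrix).
    """

    scores: np.ndarray  # (n_signatures, n_cells)
    signature_names: list[str]
    cell_ids: list[str]
    corrected: bool = True
    gene_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape != (len(self.signature_names), len(self.cell_ids)):
            raise ValueError("score matrix shape mismatch")
        if len(set(self.signature_names)) != len(self.signature_names):
            raise ValueError("duplicate signature names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.signature_names, columns=self.cell_ids)

    def row(self, name: str) -> np.ndarray:
        return self.scores[self.signature_names.index(name)]


def cell_moments(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean and population (1/N) variance over all genes."""
    mean = expr.values.mean(axis=0)
    var = expr.values.var(axis=0)  # ddof=0: population variance
    return mean, var


def match_genes(
    expr: ExpressionMatrix, sig: GeneSignature
) -> tuple[np.ndarray, np.ndarray]:
    """Case-insensitive intersection of signature genes with matrix rows."""
    index = expr.gene_index()
    pos = np.array(
        sorted(index[g.upper()] for g in sig.positive_genes if g.upper() in index),
        dtype=int,
    )
    neg = np.array(
        sorted(index[g.upper()] for g in sig.negative_genes if g.upper() in index),
        dtype=int,
    )
    return pos, neg


def raw_score(
    expr: ExpressionMatrix, sig: GeneSignature
) -> tuple[np.ndarray, int, int]:
    """Mean positive-gene minus negative-gene expression per cell.

    Returns ``(scores, n_pos_used, n_neg_used)``; the denominator counts
    only genes actually present in the matrix.  Raises ``ValueError`` when
    no signature gene matches.
    """
    pos, neg = match_genes(expr, sig)
    n, m = len(pos), len(neg)
    if n + m == 0:
        raise ValueError(f"signature {sig.name}: no genes found in expression matrix")
    total = np.zeros(expr.n_cells)
    if n:
        total += expr.values[pos].sum(axis=0)
    if m:
        total -= expr.values[neg].sum(axis=0)
    return total / (n + m), n, m


def corrected_score(
    raw: np.ndarray,
    expr: ExpressionMatrix,
    n_pos: int,
    n_neg: int,
    moments: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Z-normalize raw scores against the analytic random-signature moments.

    Cells with zero expression variance (constant rows) cannot be
    corrected; their score is set to 0 with a warning.
    """
    if n_pos + n_neg < 1:
        raise ValueError("need at least one signature gene")
    mean, var = cell_moments(expr) if moments is None else moments
    size = n_pos + n_neg
    exp_r = ((n_pos - n_neg) / size) * mean
    var_r = var / size
    out = np.zeros_like(np.asarray(raw, dtype=float))
    ok = var_r > 0
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} constant-expression cells: corrected score set to 0"
        )
    out[ok] = (raw[ok] - exp_r[ok]) / np.sqrt(var_r[ok])
    return out


def _coefficient_matrix(
    expr: ExpressionMatrix, sigs: list[GeneSignature]
) -> tuple[scipy.sparse.csr_matrix, np.ndarray, np.ndarray, list[str]]:
    """Sparse (signatures x genes) +-1/(n+m) coefficients for batch scoring."""
    rows, cols, vals = [], [], []
    n_used = np.zeros(len(sigs), dtype=int)
    m_used = np.zeros(len(sigs), dtype=int)
    usable: list[str] = []
    for i, sig in enumerate(sigs):
        pos, neg = match_genes(expr, sig)
        n_used[i], m_used[i] = len(pos), len(neg)
        size = len(pos) + len(neg)
        if size == 0:
            continue
        usable.append(sig.name)
        for g in pos:
            rows.append(i), cols.append(g), vals.append(1.0 / size)
        for g in neg:
            rows.append(i), cols.append(g), vals.append(-1.0 / size)
    coeff = scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(sigs), expr.n_genes)
    )
    return coeff, n_used, m_used, usable


def score_all(
    expr: ExpressionMatrix,
    sigs: list[GeneSignature],
    correct: bool = True,
) -> SignatureScoreMatrix:
    """Score a batch of signatures; vectorized over the whole set.

    Signatures with no usable genes are dropped and recorded in the
    result's ``dropped`` report rather than raising.
    """
    if not sigs:
        raise ValueError("empty signature list")
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate signature names")
    coeff, n_used, m_used, usable = _coefficient_matrix(expr, sigs)
    raw = np.asarray(coeff @ expr.values)  # (S, C)
    dropped = {
        s.name: "no signature genes in expression matrix"
        for i, s in enumerate(sigs)
        if n_used[i] + m_used[i] == 0
    }
    if dropped:
        warnings.warn(f"dropped {len(dropped)} signatures with no matching genes")
    keep = np.array([n_used[i] + m_used[i] > 0 for i in range(len(sigs))])
    raw = raw[keep]
    n_k, m_k = n_used[keep], m_used[keep]
    if correct and raw.size:
        mean, var = cell_moments(expr)
        size = (n_k + m_k).astype(float)[:, None]
        exp_r = ((n_k - m_k)[:, None] / size) * mean[None, :]
        var_r = var[None, :] / size
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = (raw - exp_r) / np.sqrt(var_r)
        bad = ~np.isfinite(scores)
        if bad.any():
            warnings.warn("constant-expression cells: corrected scores set to 0")
            scores[bad] = 0.0
    else:
        scores = raw
    kept_names = [s.name for s, k in zip(sigs, keep) if k]
    counts = {
        s.name: (int(n_used[i]), int(m_used[i]))
        for i, s in enumerate(sigs)
        if keep[i]
    }
    return SignatureScoreMatrix(
        scores=scores.reshape(len(kept_names), expr.n_cells),
        signature_names=kept_names,
        cell_ids=list(expr.cell_ids),
        corrected=correct,
        gene_counts=counts,
        dropped=dropped,
    )


def gene_signature_covariance(
    expr: ExpressionMatrix, scores: np.ndarray, sig: GeneSignature
) -> pd.Series:
    """Covariance of each signature gene's expression with the score.

    Used to rank which genes drive a signature's per-cell variation in
    reports.  Population covariance across cells.
    """
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells for a covariance")
    scores = np.asarray(scores, dtype=float)
    pos, neg = match_genes(expr, sig)
    idx = np.concatenate([pos, neg]).astype(int)
    sub = expr.values[idx]
    centered = sub - sub.mean(axis=1, keepdims=True)
    s_c = scores - scores.mean()
    cov = centered @ s_c / expr.n_cells
    return pd.Series(cov, index=[expr.gene_ids[i] for i in idx], name=sig.name)
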