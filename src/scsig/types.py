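"""Shared domain types.

The central containers are deliberately thin dataclasses around numpy
arrays: an :class:`ExpressionMatrix` (genes x cells, normalized log-scale
expression), a :class:`GeneSignature` (signed gene set with +1/-1
coefficients), per-cell :class:`MetaData`, a :class:`LatentSpace`
(cells x dims) and a :class:`TrajectoryModel` (milestone network with
per-cell edge positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "MetaData",
    "LatentSpace",
    "TrajectoryModel",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression with identifiers.

    ``values`` holds normalized, log-scaled expression (unitless); raw
    counts are also carried in this container prior to
    :func:`scsig.io.normalize_expression`.
    """

    values: np.ndarray  # (n_genes, n_cells), dense float
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        """Case-insensitive gene symbol -> row index (first occurrence wins)."""
        idx: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            idx.setdefault(g.upper(), i)
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            self.values[rows],
            [self.gene_ids[i] for i in rows],
            list(self.cell_ids),
        )

    def subset_cells(self, cols: np.ndarray) -> "ExpressionMatrix":
        cols = np.asarray(cols)
        return ExpressionMatrix(
            self.values[:, cols],
            list(self.gene_ids),
            [self.cell_ids[i] for i in cols],
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set; signed signatures carry a negative subset.

    Coefficients are restricted to +1 (``positive_genes``) and -1
    (``negative_genes``); an unsigned signature has an empty negative set.
    """

    name: str
    positive_genes: frozenset[str]
    negative_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive_genes", frozenset(self.positive_genes))
        object.__setattr__(self, "negative_genes", frozenset(self.negative_genes))
        overlap = self.positive_genes & self.negative_genes
        if overlap:
            raise ValueError(f"{self.name}: genes in both sets: {sorted(overlap)[:5]}")
        if len(self.positive_genes) + len(self.negative_genes) < 1:
            raise ValueError(f"{self.name}: empty signature")

    @property
    def signed(self) -> bool:
        return len(self.negative_genes) > 0

    @property
    def size(self) -> int:
        return len(self.positive_genes) + len(self.negative_genes)

    @property
    def balance(self) -> float:
        """Fraction of genes in the positive set (1.0 for unsigned)."""
        return len(self.positive_genes) / self.size


@dataclass
class MetaData:
    """Per-cell annotation table split into numeric and categorical columns."""

    cell_ids: list[str]
    numeric: pd.DataFrame = field(default_factory=pd.DataFrame)
    categorical: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.cell_ids, "cell ids")
        for df in (self.numeric, self.categorical):
            if df.shape[1] and len(df) != len(self.cell_ids):
                raise ValueError("meta-data columns must align with cell_ids")
        if not self.numeric.empty:
            self.numeric.index = pd.Index(self.cell_ids)
        if not self.categorical.empty:
            self.categorical.index = pd.Index(self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetaData":
        """Split a cell-indexed frame into numeric and categorical parts."""
        num_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        cat_cols = [c for c in df.columns if c not in num_cols]
        return cls(
            cell_ids=[str(i) for i in df.index],
            numeric=df[num_cols].astype(float),
            categorical=df[cat_cols].astype(str),
        )

    def align(self, cell_ids: list[str]) -> "MetaData":
        """Reorder rows to a cell ordering; raise on missing cells."""
        missing = [c for c in cell_ids if c not in set(self.cell_ids)]
        if missing:
            raise KeyError(f"cells missing from meta-data: {missing[:5]}")
        num = self.numeric.loc[cell_ids] if not self.numeric.empty else pd.DataFrame()
        cat = (
            self.categorical.loc[cell_ids]
            if not self.categorical.empty
            else pd.DataFrame()
        )
        return MetaData(list(cell_ids), num.reset_index(drop=True), cat.reset_index(drop=True))


@dataclass
class LatentSpace:
    """Cells x dims coordinates of a low-dimensional representation."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coords rows must match cell_ids")
        if self.coords.shape[1] < 1:
            raise ValueError("latent space needs >= 1 dimension")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("latent coordinates must be finite")
        _check_unique(self.cell_ids, "cell ids")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectoryModel:
    """Milestone network plus fractional cell positions along its edges.

    ``edges`` maps (from_milestone, to_milestone) -> length.  Each cell sits
    on one edge at ``progress`` in [0, 1] measured from the edge's "from"
    endpoint, following the common trajectory abstraction used by
    trajectory-inference wrappers.
    """

    milestones: list[str]
    edges: list[tuple[str, str, float]]
    cell_ids: list[str]
    cell_edges: list[tuple[str, str]]
    progress: np.ndarray

    def __post_init__(self) -> None:
        self.progress = np.asarray(self.progress, dtype=float)
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.milestones, "milestones")
        known = set(self.milestones)
        for a, b, ln in self.edges:
            if a not in known or b not in known:
                raise ValueError(f"edge ({a},{b}) references unknown milestone")
            if ln <= 0:
                raise ValueError(f"edge ({a},{b}) has non-positive length {ln}")
        edge_set = {(a, b) for a, b, _ in self.edges} | {
            (b, a) for a, b, _ in self.edges
        }
        for cid, e in zip(self.cell_ids, self.cell_edges):
            if tuple(e) not in edge_set:
                raise ValueError(f"cell {cid} assigned to unknown edge {e}")
        if np.any((self.progress < 0) | (self.progress > 1)):
            raise ValueError("progress must lie in [0, 1]")
        if len(self.cell_edges) != len(self.cell_ids) or len(self.progress) != len(
            self.cell_ids
        ):
            raise ValueError("cell_edges and progress must align with cell_ids")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)
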