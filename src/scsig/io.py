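"""Readers and writers for the formats the pipeline touches.

Expression comes in as MatrixMarket triplets (with sidecar gene / cell
name files) or as a TSV with a header row of cell ids; signatures as GMT;
meta-data as a TSV keyed by cell id; latent spaces as a cells x dims TSV;
trajectories as a small JSON document describing the milestone network and
per-cell edge positions.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionMatrix, GeneSignature, LatentSpace, MetaData, TrajectoryModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "normalize_expression",
    "read_signatures",
    "write_signatures",
    "read_metadata",
    "write_metadata",
    "read_latent",
    "write_latent",
    "read_trajectory",
    "write_trajectory",
]


def _dedupe_genes(values: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Resolve duplicate gene symbols by keeping the highest-total row."""
    ids = pd.Index(gene_ids)
    if ids.is_unique:
        return values, gene_ids
    totals = values.sum(axis=1)
    keep: dict[str, int] = {}
    for i, g in enumerate(gene_ids):
        if g not in keep or totals[i] > totals[keep[g]]:
            keep[g] = i
    n_dup = len(gene_ids) - len(keep)
    warnings.warn(f"{n_dup} duplicate gene symbols collapsed (kept highest-count row)")
    rows = sorted(keep.values())
    return values[rows], [gene_ids[i] for i in rows]


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``format`` is ``"mtx"`` or ``"tsv"``; inferred from the suffix when
    omitted.  MTX files need sidecar ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` name files (one id per line).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as e:
            raise ValueError(f"malformed MatrixMarket file {path}: {e}") from e
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        stem = path.with_suffix("")
        gene_file = Path(str(stem) + ".genes.txt")
        cell_file = Path(str(stem) + ".cells.txt")
        if not gene_file.exists() or not cell_file.exists():
            raise FileNotFoundError(
                f"MTX requires sidecar name files {gene_file} and {cell_file}"
            )
        gene_ids = gene_file.read_text().split()
        cell_ids = cell_file.read_text().split()
        if len(gene_ids) != values.shape[0] or len(cell_ids) != values.shape[1]:
            raise ValueError("sidecar name files do not match matrix dimensions")
    elif format == "tsv":
        sep = "," if path.suffix == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):  # pandas would mangle these silently
            raise ValueError(f"duplicate cell ids in {path}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as e:  # malformed header / ragged rows
            raise ValueError(f"malformed expression table {path}: {e}") from e
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    values, gene_ids = _dedupe_genes(values, gene_ids)
    return ExpressionMatrix(values, gene_ids, cell_ids)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(expr.values))
        stem = path.with_suffix("")
        Path(str(stem) + ".genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
        Path(str(stem) + ".cells.txt").write_text("\n".join(expr.cell_ids) + "\n")
    elif format == "tsv":
        expr.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def normalize_expression(
    expr: ExpressionMatrix, mode: str = "median_umi", log1p: bool = True
) -> ExpressionMatrix:
    """Library-size normalize raw counts and optionally log(x+1) transform.

    ``median_umi`` scales each cell's total to the median total across
    cells (the convention used for UMI data); ``cpm`` scales to 1e6;
    ``none`` leaves totals untouched.  Cells with zero total counts are
    dropped with a warning since downstream score correction divides by
    the per-cell expression variance.
    """
    if mode not in ("median_umi", "cpm", "none"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = expr.values
    if mode != "none" and np.any(values < 0):
        raise ValueError("library-size normalization expects non-negative counts")
    totals = values.sum(axis=0)
    nonzero = totals > 0
    if not np.all(nonzero):
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero cells")
        values = values[:, nonzero]
        totals = totals[nonzero]
        cell_ids = [c for c, ok in zip(expr.cell_ids, nonzero) if ok]
    else:
        cell_ids = list(expr.cell_ids)
    if mode == "median_umi":
        target = float(np.median(totals))
        values = values * (target / totals)
    elif mode == "cpm":
        values = values * (1e6 / totals)
    else:
        values = values.copy()
    if log1p:
        values = np.log1p(values)
    return ExpressionMatrix(values, list(expr.gene_ids), cell_ids)


def _parse_gene_token(tok: str) -> tuple[str, int]:
    """Parse an optional inline sign suffix: ``"GENE,-1"`` or ``"GENE,1"``."""
    if "," in tok:
        gene, _, sign = tok.rpartition(",")
        sign = sign.strip()
        if sign in ("1", "+1"):
            return gene, +1
        if sign == "-1":
            return gene, -1
    return tok, +1


def read_signatures(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file into signatures.

    Two dialects encode signed signatures: a name-pair convention where
    ``NAME_PLUS`` and ``NAME_MINUS`` lines merge into one signed signature
    ``NAME``, and an inline per-gene suffix ``GENE,-1``.  Plain lines yield
    unsigned signatures.
    """
    path = Path(path)
    raw: dict[str, tuple[set[str], set[str]]] = {}
    order: list[str] = []
    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        n_lines += 1
        fields = line.split("\t")
        if len(fields) < 3:
            warnings.warn(f"{path}:{lineno}: fewer than 3 fields, skipping")
            continue
        name, _desc, *genes = fields
        genes = [g.strip() for g in genes if g.strip()]
        pos: set[str] = set()
        neg: set[str] = set()
        for tok in genes:
            gene, sign = _parse_gene_token(tok)
            (pos if sign > 0 else neg).add(gene)
        upper = name.upper()
        if upper.endswith("_PLUS"):
            base, part = name[: -len("_PLUS")], "pos"
        elif upper.endswith("_MINUS"):
            base, part = name[: -len("_MINUS")], "neg"
        else:
            base, part = name, "pos"
        if base not in raw:
            raw[base] = (set(), set())
            order.append(base)
        if part == "pos":
            raw[base][0].update(pos)
            raw[base][1].update(neg)
        else:
            # a _MINUS line contributes its genes to the negative set
            raw[base][1].update(pos)
            raw[base][0].update(neg)
    if n_lines == 0:
        raise ValueError(f"empty GMT file: {path}")
    sigs = []
    for name in order:
        pos, neg = raw[name]
        pos, neg = pos - neg, neg - pos  # a gene listed both ways cancels
        if not pos and not neg:
            warnings.warn(f"signature {name} empty after sign resolution, skipping")
            continue
        sigs.append(GeneSignature(name, frozenset(pos), frozenset(neg)))
    if not sigs:
        raise ValueError(f"no valid signatures in {path}")
    return sigs


def write_signatures(sigs: list[GeneSignature], path: str | Path) -> None:
    """Write GMT using the inline ``GENE,-1`` suffix for negative genes."""
    lines = []
    for s in sigs:
        genes = sorted(s.positive_genes) + [f"{g},-1" for g in sorted(s.negative_genes)]
        lines.append("\t".join([s.name, "na"] + genes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> MetaData:
    """Read a meta-data TSV whose first column holds cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return MetaData.from_frame(df)


def write_metadata(meta: MetaData, path: str | Path) -> None:
    df = pd.concat([meta.numeric, meta.categorical], axis=1)
    df.index = pd.Index(meta.cell_ids, name="cell_id")
    df.to_csv(path, sep="\t")


def read_latent(path: str | Path) -> LatentSpace:
    """Read a cells x dims TSV (first column = cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LatentSpace(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_latent(latent: LatentSpace, path: str | Path) -> None:
    df = pd.DataFrame(
        latent.coords,
        index=pd.Index(latent.cell_ids, name="cell_id"),
        columns=[f"dim_{i+1}" for i in range(latent.coords.shape[1])],
    )
    df.to_csv(path, sep="\t")


def read_trajectory(path: str | Path) -> TrajectoryModel:
    """Read a trajectory JSON: milestone network plus per-cell positions.

    Schema::

        {"milestones": ["A", ...],
         "edges": [{"from": "A", "to": "B", "length": 1.5}, ...],
         "cells": [{"id": "c1", "edge_from": "A", "edge_to": "B",
                    "progress": 0.3}, ...]}
    """
    doc = json.loads(Path(path).read_text())
    return TrajectoryModel(
        milestones=[str(m) for m in doc["milestones"]],
        edges=[(str(e["from"]), str(e["to"]), float(e["length"])) for e in doc["edges"]],
        cell_ids=[str(c["id"]) for c in doc["cells"]],
        cell_edges=[(str(c["edge_from"]), str(c["edge_to"])) for c in doc["cells"]],
        progress=np.array([float(c["progress"]) for c in doc["cells"]]),
    )


def write_trajectory(traj: TrajectoryModel, path: str | Path) -> None:
    doc = {
        "milestones": traj.milestones,
        "edges": [{"from": a, "to": b, "length": ln} for a, b, ln in traj.edges],
        "cells": [
            {"id": cid, "edge_from": e[0], "edge_to": e[1], "progress": float(p)}
            for cid, e, p in zip(traj.cell_ids, traj.cell_edges, traj.progress)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
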