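"""End-to-end orchestration: config -> results bundle on disk.

The run order mirrors the analysis design: normalize -> (optional
micro-pooling) -> signature scores -> neighbor graph (latent space or
trajectory) -> autocorrelation with background nulls -> meta-data tests ->
optional differential and latent-component annotation.  Everything is
driven by one :class:`RunConfig`, one seed, and writes a flat directory of
TSVs plus a JSON index for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .autocorr import analyze_signatures, metadata_numeric_autocorrelation
from .categorical import metadata_categorical_autocorrelation
from .differential import one_vs_all
from .io import (
    normalize_expression,
    read_expression,
    read_latent,
    read_metadata,
    read_signatures,
    read_trajectory,
)
from .lcannot import annotate_components
from .micropool import micropool
from .neighbors import knn_from_latent, knn_from_trajectory, weights_from_distances
from .scoring import score_all
from .types import ExpressionMatrix, LatentSpace

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "pca_latent"]


def pca_latent(expr: ExpressionMatrix, n_components: int = 20, seed: int = 0) -> LatentSpace:
    """Convenience PCA latent space from gene-standardized expression."""
    from sklearn.decomposition import PCA

    x = expr.values.T
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    coords = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    return LatentSpace(coords, list(expr.cell_ids))


@dataclass
class RunConfig:
    """All inputs and parameters of a pipeline run.

    Serialized verbatim into the output bundle so every result is
    reproducible from the bundle alone.
    """

    expression: str
    signatures: str
    output_dir: str
    latent: str | None = None
    trajectory: str | None = None
    metadata: str | None = None
    normalize: str = "median_umi"  # median_umi | cpm | none
    log1p: bool = True
    k: int | None = None  # None -> ceil(sqrt(N))
    bandwidth: str = "squared"  # kernel dialect: squared | literal
    n_backgrounds: int = 500
    n_permutations: int = 1000
    pool_size: int | None = None  # enable micro-pooling when set
    differential_by: str | None = None  # categorical column for 1-vs-all
    lc_annotate: bool = False
    n_pca: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if self.latent and self.trajectory:
            raise ValueError("provide a latent space or a trajectory, not both")
        if self.trajectory and self.pool_size:
            raise ValueError("micro-pooling is not defined for trajectory input")
        if self.bandwidth not in ("squared", "literal"):
            raise ValueError("bandwidth must be 'squared' or 'literal'")
        for name in ("expression", "signatures", "latent", "trajectory", "metadata"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _write_tsv(df, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
    written.append(path)


def run(config: RunConfig) -> dict:
    """Execute the configured analysis and write the results bundle.

    Returns the JSON index (also written to ``bundle.json``).  On error,
    any partially written outputs are removed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_inner(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_inner(config: RunConfig, out: Path, written: list[Path]) -> dict:
    stage = "read"
    try:
        expr = read_expression(config.expression)
        sigs = read_signatures(config.signatures)
        meta = read_metadata(config.metadata) if config.metadata else None

        stage = "normalize"
        expr = normalize_expression(expr, mode=config.normalize, log1p=config.log1p)
        if meta is not None:
            meta = meta.align(expr.cell_ids)

        pooled = False
        if config.pool_size is not None and config.pool_size < expr.n_cells:
            stage = "micropool"
            assignment, expr = micropool(expr, config.pool_size, seed=config.seed)
            _write_tsv(assignment.to_frame(), out / "pool_assignment.tsv", written)
            pooled = True
            meta = None  # per-cell annotations do not transfer to pools
            logger.info("pooled %d cells into %d pools", len(assignment.cell_ids), assignment.n_pools)

        stage = "scores"
        scores = score_all(expr, sigs)
        df = scores.to_frame()
        df.insert(0, "signature", df.index)
        _write_tsv(df, out / "scores.tsv", written)
        if scores.dropped:
            import pandas as pd

            _write_tsv(
                pd.DataFrame(
                    {"signature": list(scores.dropped), "reason": list(scores.dropped.values())}
                ),
                out / "dropped_signatures.tsv",
                written,
            )

        stage = "graph"
        if config.trajectory:
            traj = read_trajectory(config.trajectory)
            if traj.cell_ids != expr.cell_ids:
                raise ValueError("trajectory cells do not match expression cells")
            graph = knn_from_trajectory(traj, config.k)
        else:
            if config.latent:
                latent = read_latent(config.latent)
                if not pooled and latent.cell_ids != expr.cell_ids:
                    raise ValueError("latent cells do not match expression cells")
                if pooled:
                    latent = pca_latent(expr, config.n_pca, config.seed)
            else:
                latent = pca_latent(expr, config.n_pca, config.seed)
            graph = knn_from_latent(latent, config.k)
        if config.bandwidth != "squared":
            graph = weights_from_distances(graph, bandwidth=config.bandwidth)

        stage = "autocorrelation"
        autocorr = analyze_signatures(
            expr, sigs, graph, n_background=config.n_backgrounds,
            seed=config.seed, scores=scores,
        )
        _write_tsv(autocorr, out / "autocorrelation.tsv", written)

        if meta is not None and not meta.numeric.empty:
            stage = "metadata-numeric"
            num = metadata_numeric_autocorrelation(
                meta, graph, n_perm=config.n_permutations, seed=config.seed
            )
            _write_tsv(num, out / "metadata_numeric.tsv", written)
        if meta is not None and not meta.categorical.empty:
            stage = "metadata-categorical"
            cat = metadata_categorical_autocorrelation(meta.categorical, graph)
            _write_tsv(cat, out / "metadata_categorical.tsv", written)

        if config.differential_by and meta is not None:
            stage = "differential"
            if config.differential_by not in meta.categorical.columns:
                raise KeyError(f"no categorical column {config.differential_by!r}")
            labels = meta.categorical[config.differential_by].to_numpy()
            _write_tsv(one_vs_all(scores, labels), out / "differential.tsv", written)

        if config.lc_annotate and not config.trajectory:
            stage = "lcannotator"
            lc = annotate_components(latent, scores, meta)
            _write_tsv(lc, out / "lc_annotations.tsv", written)

        stage = "bundle"
        index = {
            "version": __version__,
            "seed": config.seed,
            "pooled": pooled,
            "n_cells": expr.n_cells,
            "n_genes": expr.n_genes,
            "k": graph.k,
            "files": sorted([p.name for p in written] + ["bundle.json"]),
            "config": dataclasses.asdict(config),
        }
        bundle = out / "bundle.json"
        bundle.write_text(json.dumps(index, indent=1))
        written.append(bundle)
        return index
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e
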