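import numpy as np
import pytest

from scsig import (
    ExpressionMatrix,
    GeneSignature,
    LatentSpace,
    PlantedSignature,
    SyntheticSpec,
    knn_from_latent,
    make_clustered_dataset,
    normalize_expression,
    pca_latent,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """50 genes x 30 cells of positive log-scale expression."""
    values = rng.gamma(2.0, 1.0, size=(50, 30))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(50)],
        [f"c{j}" for j in range(30)],
    )


@pytest.fixture
def clustered():
    """Two 100-cell clusters with one planted 30-gene signature (+1.5 log-units)."""
    spec = SyntheticSpec(
        n_cells=200,
        n_genes=300,
        n_clusters=2,
        planted_signatures=[
            PlantedSignature("planted", n_genes=30, affected_clusters=(0,), effect_size=1.5)
        ],
        seed=7,
    )
    counts, meta, sigs = make_clustered_dataset(spec)
    expr = normalize_expression(counts)
    return expr, meta, sigs


@pytest.fixture
def clustered_graph(clustered):
    expr, meta, sigs = clustered
    latent = pca_latent(expr, 10, seed=7)
    return knn_from_latent(latent)


@pytest.fixture
def line_graph():
    """30 cells on a line; a 1-D chain-like KNN graph."""
    coords = np.arange(30, dtype=float)[:, None]
    latent = LatentSpace(coords, [f"c{i}" for i in range(30)])
    return knn_from_latent(latent, k=4)


def random_signature(rng, gene_ids, n_pos, n_neg=0, name="sig"):
    chosen = rng.choice(len(gene_ids), size=n_pos + n_neg, replace=False)
    genes = [gene_ids[i] for i in chosen]
    return GeneSignature(name, frozenset(genes[:n_pos]), frozenset(genes[n_pos:]))
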