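"""Label-free analysis: which signatures vary coherently on the cell manifold?

Builds a synthetic dataset of two cell populations where a 30-gene
signature is up-regulated (+1.5 natural-log units) in one of them, scores
every cell, and asks whether the signature's scores are locally
autocorrelated on the KNN graph of a PCA latent space.  The C' statistic
(1 - Geary's C on score ranks) is near 0 for noise and approaches 1 for a
signature that tracks the manifold; significance comes from random
signatures matched in size.
"""

import numpy as np

from scsig import (
    PlantedSignature,
    SyntheticSpec,
    analyze_signatures,
    knn_from_latent,
    make_clustered_dataset,
    normalize_expression,
    pca_latent,
    score_all,
)

spec = SyntheticSpec(
    n_cells=600,
    n_genes=800,
    n_clusters=2,
    planted_signatures=[
        PlantedSignature("planted_response", n_genes=30, affected_clusters=(0,), effect_size=1.5),
        PlantedSignature("null_geneset", n_genes=30, affected_clusters=(0,), effect_size=0.0),
    ],
    seed=0,
)
counts, meta, signatures = make_clustered_dataset(spec)
expr = normalize_expression(counts)  # median-UMI scaling + log1p

latent = pca_latent(expr, n_components=10, seed=0)
graph = knn_from_latent(latent)  # K = ceil(sqrt(600)) = 25

results = analyze_signatures(expr, signatures, graph, n_background=200, seed=0)
print(results.round(4).to_string(index=False))
print(
    "\nThe planted signature shows high C' with a small FDR (it varies"
    "\nsmoothly across the manifold); the zero-effect gene set behaves like"
    "\na random signature: C' near 0 and a non-significant p-value."
)
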