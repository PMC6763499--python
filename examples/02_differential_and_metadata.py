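"""Label-based analysis: differential signatures and meta-data structure.

With cluster labels in hand, every signature is tested 1-vs-all per level
(Wilcoxon rank-sum, AUROC effect size).  Meta-data are tested too:
categorical variables (batch, donor) with the local-proportion chi-squared
test and Cramér's V; numeric covariates with a permutation test of their
rank autocorrelation.
"""

import pandas as pd

from scsig import (
    PlantedSignature,
    SyntheticSpec,
    knn_from_latent,
    make_clustered_dataset,
    metadata_categorical_autocorrelation,
    metadata_numeric_autocorrelation,
    normalize_expression,
    one_vs_all,
    pca_latent,
    score_all,
)

spec = SyntheticSpec(
    n_cells=500,
    n_genes=600,
    n_clusters=2,
    planted_signatures=[PlantedSignature("stim_response", 40, (0,), 1.5)],
    seed=1,
)
counts, meta, signatures = make_clustered_dataset(spec)
expr = normalize_expression(counts)
graph = knn_from_latent(pca_latent(expr, 10, seed=1))

scores = score_all(expr, signatures)
labels = meta.categorical["cluster"].to_numpy()
print("--- 1-vs-all differential signatures ---")
print(one_vs_all(scores, labels).round(4).to_string(index=False))
print(
    "AUROC 1.0 for cluster_0 means every cluster_0 cell outranks every"
    "\nother cell on this signature; 0.5 would mean no separation.\n"
)

print("--- categorical meta-data (local-neighborhood association) ---")
print(metadata_categorical_autocorrelation(meta.categorical, graph).round(4).to_string(index=False))
print(
    "'cluster' is perfectly localized on the graph (V near 1);"
    "\n'donor' was assigned at random, so V stays near 0.\n"
)

print("--- numeric meta-data (permutation test on rank autocorrelation) ---")
# cell detection ratio: fraction of genes detected per cell, a standard QC covariate
cdr = (counts.values > 0).mean(axis=0)
meta.numeric["detection_ratio"] = cdr
print(metadata_numeric_autocorrelation(meta, graph, n_perm=200, seed=1).round(4).to_string(index=False))
print("A small p flags a covariate that tracks the manifold (a possible confounder).")
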