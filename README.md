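# scsig

**Annotate the sources of variation in single-cell RNA-seq data with gene
signatures.**

Single-cell experiments routinely produce a low-dimensional map of cells —
a PCA/scVI latent space, or an inferred trajectory — but the map itself
says nothing about *which biological programs* drive its structure. `scsig`
answers that question for anyone with a normalized expression matrix, a
library of gene signatures (e.g. MSigDB GMT files) and, optionally,
per-cell meta-data: it scores every cell against every signature, then
tests which signatures (and which meta-data variables) vary coherently
along the cell–cell similarity map, with no clustering required.

## The method

**Signature scores.** For a signature with positive gene set G_pos
(n genes) and negative set G_neg (m genes), the raw score of cell *j* on
normalized log-scale expression e is

    s_j = ( Σ_{g∈G_pos} e_gj − Σ_{g∈G_neg} e_gj ) / (n + m)

Raw scores correlate with per-cell technical covariates (library size,
detection rate), so each score is z-normalized against the analytic
moments of a *random* signature of the same size and balance:

    E[R_j] = ((n − m)/(n + m))·ē_j      var(R_j) = σ_j²/(n + m)
    s′_j = (s_j − E[R_j]) / var(R_j)^½

with ē_j, σ_j² the mean and variance of cell *j*'s expression over all
genes.

**Local autocorrelation.** Each cell is linked to its K = ⌈√N⌉ nearest
neighbors (Euclidean in the latent space, or geodesic through a
trajectory's milestone network) with Gaussian weights
w_ij = exp(−d_ij²/σ_i²), σ_i the distance to the K-th neighbor. The
statistic is Geary's C on the *ranks* x of the corrected scores,

    C = (N−1) Σ_ij w_ij (x_i − x_j)² / ( 2W Σ_i (x_i − x̄)² )

reported as C′ = 1 − C, so 0 means no local structure and 1 maximal
smoothness on the map. Significance comes from an empirical null of
random signatures matched in size and sign balance (five k-means groups
over log₁₀ size × balance), pushed through the *identical*
score → rank → C′ pipeline; p = (x+1)/(n_bg+1) one-sided, BH-corrected.

**Beyond label-free autocorrelation**, the package provides: 1-vs-all
differential signature tests per categorical label (Wilcoxon rank-sum,
AUROC effect size); a chi-squared / Cramér's V test for how strongly a
discrete variable (batch, donor) is localized on the graph; permutation
tests for numeric covariates (optionally stratified, e.g. within-donor);
Spearman annotation of individual latent components; and micro-pooling
(Louvain + K-means partitions of at most P cells, replaced by their mean
profiles) to scale all of the above to very large datasets.

## Worked example

`examples/01_signature_autocorrelation.py` simulates 600 cells in two
populations, one carrying a 30-gene signature up-regulated by 1.5
log-units, scores the cells and tests autocorrelation on a 10-dim PCA
graph against 200 random background signatures:

```
       signature  c_prime  p_value    fdr  background_group
planted_response   0.7898   0.0050 0.0100                 0
    null_geneset   0.0836   0.0896 0.0896                 0
```

The planted signature varies smoothly across the manifold (C′ = 0.79,
FDR = 0.01 — no random signature reached its C′), while a zero-effect
gene set of the same size behaves like the null (C′ ≈ 0.08, not
significant). The other scripts in `examples/` walk through differential
and meta-data tests, trajectory mode, micro-pooling and the end-to-end
pipeline with its HTML report; each prints the numbers it computes and a
line on how to read them.

A thin CLI wraps the same pipeline:

```bash
scsig simulate data/ --n-cells 1000
scsig run config.yaml --seed 1        # normalize → score → graph → tests
scsig report out/                     # one self-contained HTML page
```

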