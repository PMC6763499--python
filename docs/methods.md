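# Methods

This note records the models and procedures `scsig` implements, the
defaults and why, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signature scores and the random-signature correction

Scores are means of normalized log-scale expression over the signature's
genes, positive minus negative, divided by the total number of genes
*used*. Genes absent from the matrix are intersected away first and the
counts n, m refer to the genes actually used, so a signature whose genes
are partially missing keeps a consistent scale between the raw score and
its correction. Matching is case-insensitive on the exact symbol; no
identifier-version stripping is attempted. A signature with no usable
genes is dropped and reported, not an error.

The correction z-normalizes against a random signature of the same
(n, m): E[R_j] = ((n−m)/(n+m))·ē_j and var(R_j) = σ_j²/(n+m), where ē_j
and σ_j² are the mean and *population* (1/N) variance of cell j over
**all** genes of the filtered matrix — the gene universe a random
signature is drawn from — not just the signature's genes. The variance
formula treats the n+m draws as independent; drawing without replacement
from G genes would multiply it by (G−(n+m))/(G−1). We keep the formula as
stated because the matched empirical background (below) absorbs any
common distortion; the practical consequence is that corrected scores of
random signatures have variance slightly below 1 (≈0.95 for 50 genes
from a 1000-gene universe), which the calibration tests account for.
Cells with zero expression variance cannot be corrected; their score is
set to 0 with a warning (they are normally removed earlier: library-size
normalization drops all-zero cells).

## Neighbor graphs

Default K = ⌈√N⌉. The kernel is w_ij = exp(−d_ij²/σ_i²). The bandwidth
is described in terms of the distance d_iK to the K-th neighbor, which
leaves two readings; the default takes σ_i = d_iK so the exponent
d²/σ² is dimensionless and equals 1 at the neighborhood boundary
(weight e⁻¹). The alternative reading (σ_i² = d_iK literally) is exposed
as `bandwidth: literal`. Rows whose K-th neighbor is at distance 0
(duplicate points) get uniform weight 1.

The graph is directed: Geary's C sums over the stored pairs
(i, j ∈ KNN(i)) exactly as the formula is written, with W the total
stored weight. A symmetrized view ((w_ij+w_ji)/2 over the union) is
available on the graph object for sensitivity analysis but is not used
by default. Cells are never their own neighbors. Distance ties at the
K-boundary are broken by cell index (stable sort), making graphs
deterministic. Exact KNN (chunked brute force) is used up to 20,000
cells; beyond that a tree index takes over.

Trajectory input is a milestone network (edges with lengths) plus a
per-cell edge assignment and fractional progress. The cell–cell distance
is the geodesic through the network: min over the two endpoint routes of
each cell's edge, with cells sharing an edge also connected directly
along it. The network must be connected; the error names the components.

## Autocorrelation significance

The value vector for Geary's C is the within-signature average-tie rank
of the corrected scores, so C′ is invariant to monotone transforms and
robust to heavy tails. Input signatures are clustered by (log₁₀ size,
balance = n/(n+m)) with seeded k-means, k = 5 (fewer if fewer
signatures); each cluster center defines a background group: 500 (by
default; configurable, tests use 100–500) random signatures of the
center's rounded size and balance drawn uniformly without replacement
from the matrix's genes, the first ⌈balance·size⌉ of each draw assigned
to the positive set. Background signatures flow through the *same*
score → rank → C′ path, so the null reflects the whole pipeline. The
p-value is one-sided, p = (x+1)/(n_bg+1) with x the count of null C′ at
or above the observed value; the full group null is shared by all
signatures assigned to that group. BH correction is applied within
separate families: transcriptional signatures, numeric meta-data, and
categorical meta-data each on their own.

Numeric meta-data columns (library size, detection ratio, or any
user-supplied per-cell statistic) are rank-transformed and tested by
permutation (default 1000), since no random-signature null exists for
them; `stratify_by` confines permutations within the levels of a
categorical column, which removes between-group signal (e.g. a
donor-offset control). One RNG seed governs backgrounds, permutations
and k-means initialization.

## Categorical meta-data

Local label distributions ĉ_im = Σ_j w_ij I_m(c_j) are aggregated into
the square table X_lm = Σ_i ĉ_im I_l(c_i) and evaluated with a Pearson
chi-squared test; the effect size is Cramér's V = √(χ²/(T(L−1))). The
ĉ rows are not normalized before aggregation (the construction contains
no normalization; row masses then equal the cells' total outgoing
weights). Entries are fractional kernel-weighted counts used as-is, so
the χ² sampling distribution holds only approximately — one more reason
V, not p, is the primary ranking, as huge N makes trivially weak effects
significant anyway. No continuity correction is applied (meaningless for
fractional counts; the 2×2 hand-check [[30,10],[10,30]] gives χ² = 20,
V = 0.5). Levels empty in both margins are dropped with a warning;
single-level variables are skipped.

## Differential signatures

For each categorical stratification, every (signature, level) pair gets
a two-sided Wilcoxon rank-sum test of in-level vs all other cells, with
AUROC = U/(n₁n₂) as effect size and a direction flag (AUROC ≥ 0.5 ⇒ up).
p-values use scipy's Mann-Whitney machinery: exact enumeration for small
tie-free samples, otherwise the normal approximation with tie and
continuity correction. Levels with fewer than 2 cells are skipped with a
warning. BH is applied across all pairs of one stratification. The same
machinery runs on single-gene expression rows via `differential_genes`.

## Micro-pooling

Gene filters first: detection (nonzero in ≥10% of cells), then a
Fano-factor filter — genes are binned into 30 mean-expression quantile
bins and kept when their Fano factor (variance/mean) exceeds the bin
median plus 2 MADs; constants are configurable, and the filter falls
back to detection-only when it degenerates. The filtered matrix is
gene-standardized (log-scale input assumed) and projected to 20 PCs;
a K = ⌈√N⌉ graph is clustered with Louvain (igraph, seeded,
resolution 1); any community of size S > P is split by seeded K-means
with k = ⌈S/P⌉, re-applied until every pool has at most P cells
(default P = 20). Pooled profiles are plain means of member cells over
*all* genes of the input, so the size-weighted mean of pool columns
equals the global mean exactly. Downstream analyses weight pools
equally, not by size. Pool quality can be audited with coherence
ratios r_pi = σ_pi/σ_p (within-pool over population standard deviation
of any per-cell feature); size-1 pools report r = 0 and are flagged.

## Synthetic data

The generator emulates the statistical features the methods rely on:
gamma-Poisson (negative binomial) counts with dispersion 0.5, lognormal
library sizes with CV 0.3 (typical droplet-data magnitudes), lognormal
baseline gene means, even cluster sizes, random donor labels, planted
signature shifts in natural-log units (constant per cluster or scaled by
a per-cell uniform gradient position), and branching trajectories with
branch-marker ramps up to a configurable log-effect. It does not emulate
doublets, ambient RNA, batch chemistry or realistic gene-gene
correlation beyond the planted structure, so green tests demonstrate
correctness of the machinery and its calibration under a plausible noise
model — not biological recall on any particular tissue.

## Problem sizes and numerical choices

The validation suite exercises: oracle agreement of Geary's C against a
dense N² evaluation on graphs up to 500 cells (tolerance 1e−10; observed
agreement is at machine precision); exact AUROC pair-counting on heavily
tied samples; score calibration with 1000 random signatures on 200
cells; p-value uniformity and the ~5% type-I rate with 500 null draws
against 500 backgrounds on 300 structureless cells; planted-signal
recovery over twenty 1000-cell simulations (30-gene, +1 log-unit
signature, 500 backgrounds); ranking stability across K ∈ {10…2√N} on
900 cells; pooling consistency on 5000 cells with three planted
gradients (P = 20); and trajectory geodesics against a Dijkstra oracle
on a subdivided tree with 200 cells. These sizes were chosen as the
smallest at which each property is statistically decidable. Determinism:
every stochastic step (generators, backgrounds, permutations, k-means,
Louvain, PCA) is driven by explicit seeds, and identical configuration
plus seed reproduces byte-identical output bundles.

## Known limitations

- The empirical null matches background size/balance at the group-center
  resolution (five groups), not per signature; extremely heterogeneous
  libraries may want more groups.
- The χ² p-value for categorical variables inherits the fractional-count
  approximation; treat V as the primary quantity.
- Micro-pooling discards per-cell meta-data (labels do not transfer to
  pools); run label-based analyses on the unpooled data.
- Spatial coordinates would plug into the same machinery as a latent
  space but are untested here.
- Weighted gene coefficients beyond ±1 are out of scope by design.
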