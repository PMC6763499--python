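"""Seeded synthetic single-cell datasets with known planted structure.

Every analysis in the package can be exercised without downloads: this
module generates count matrices with configurable cluster structure,
planted signature shifts and smooth within-cluster gradients (the
clustered generator), and branching trajectories with branch-specific
marker ramps (the tree generator).  Counts follow a gamma-Poisson
(negative binomial) model with lognormal library-size variation, the
standard stylized model of droplet scRNA-seq noise.

The generators emulate the statistical features the methods rely on —
overdispersed counts, library-size covariates, cluster- and
gradient-shaped mean shifts — and none of the messier properties of real
data (doublets, ambient RNA, batch chemistry); test results therefore
speak to the correctness of the machinery, not to biological recall on
any particular tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSignature, MetaData, TrajectoryModel

__all__ = [
    "PlantedSignature",
    "SyntheticSpec",
    "make_clustered_dataset",
    "make_tree_dataset",
]


@dataclass(frozen=True)
class PlantedSignature:
    """A gene set shifted in some clusters, optionally along a gradient.

    ``effect_size`` is the shift of the (natural-)log mean expression in
    the affected clusters; with ``gradient=True`` the shift scales with a
    per-cell uniform position t in [0, 1] instead of being constant, which
    plants a smooth within-cluster axis of variation.
    """

    name: str
    n_genes: int = 50
    affected_clusters: tuple[int, ...] = (0,)
    effect_size: float = 1.0
    gradient: bool = False


@dataclass
class SyntheticSpec:
    """Study conditions for the clustered generator."""

    n_cells: int = 1000
    n_genes: int = 1000
    n_clusters: int = 2
    planted_signatures: list[PlantedSignature] = field(default_factory=list)
    n_donors: int = 2
    noise_model: str = "nb"  # "nb" (gamma-Poisson) or "lognormal"
    dispersion: float = 0.5  # NB dispersion (1/size)
    library_cv: float = 0.3  # lognormal library-size coefficient of variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("nb", "lognormal"):
            raise ValueError("noise_model must be 'nb' or 'lognormal'")
        total_planted = sum(p.n_genes for p in self.planted_signatures)
        if total_planted > self.n_genes:
            raise ValueError("planted signatures need more genes than the universe has")
        for p in self.planted_signatures:
            if any(c >= self.n_clusters or c < 0 for c in p.affected_clusters):
                raise ValueError(f"{p.name}: affected cluster out of range")
            if not np.isfinite(p.effect_size):
                raise ValueError(f"{p.name}: effect size must be finite")


def _sample_counts(rng, mean: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    if spec.noise_model == "nb":
        shape = 1.0 / spec.dispersion
        lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
    else:
        sigma = np.sqrt(np.log1p(spec.library_cv**2))
        lam = mean * rng.lognormal(-0.5 * sigma**2, sigma, size=mean.shape)
    return rng.poisson(lam).astype(float)


def make_clustered_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, MetaData, list[GeneSignature]]:
    """Generate raw counts with clusters, donors and planted signatures.

    Returns the count matrix (genes x cells), per-cell meta-data (cluster
    and donor labels, plus the latent gradient position used by
    gradient-planted signatures) and the ground-truth signatures (one
    unsigned signature per planted gene set).
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    cell_ids = [f"C{j:05d}" for j in range(spec.n_cells)]
    clusters = np.arange(spec.n_cells) % spec.n_clusters
    donors = rng.integers(0, spec.n_donors, size=spec.n_cells)
    gradient_pos = rng.uniform(0.0, 1.0, size=spec.n_cells)

    base = rng.lognormal(mean=-0.5, sigma=1.0, size=spec.n_genes)
    log_mean = np.log(base)[:, None] + np.zeros((1, spec.n_cells))

    # planted gene sets are disjoint, carved from the front of the universe
    signatures: list[GeneSignature] = []
    cursor = 0
    for planted in spec.planted_signatures:
        genes = np.arange(cursor, cursor + planted.n_genes)
        cursor += planted.n_genes
        affected = np.isin(clusters, planted.affected_clusters)
        shift = np.where(affected, planted.effect_size, 0.0)
        if planted.gradient:
            shift = shift * gradient_pos
        log_mean[np.ix_(genes, np.arange(spec.n_cells))] += shift[None, :]
        signatures.append(
            GeneSignature(planted.name, frozenset(gene_ids[g] for g in genes))
        )

    sigma_lib = np.sqrt(np.log1p(spec.library_cv**2))
    lib = rng.lognormal(-0.5 * sigma_lib**2, sigma_lib, size=spec.n_cells)
    mean = np.exp(log_mean) * lib[None, :]
    counts = _sample_counts(rng, mean, spec)

    meta = MetaData(
        cell_ids=cell_ids,
        numeric=pd.DataFrame({"gradient": gradient_pos}, index=cell_ids),
        categorical=pd.DataFrame(
            {
                "cluster": [f"cluster_{c}" for c in clusters],
                "donor": [f"donor_{d}" for d in donors],
            },
            index=cell_ids,
        ),
    )
    return ExpressionMatrix(counts, gene_ids, cell_ids), meta, signatures


def _random_tree(rng, n_milestones: int) -> list[tuple[str, str, float]]:
    """Uniform random labeled tree with lognormal edge lengths."""
    edges = []
    for child in range(1, n_milestones):
        parent = int(rng.integers(0, child))
        length = float(rng.lognormal(1.0, 0.3))
        edges.append((f"M{parent}", f"M{child}", length))
    return edges


def make_tree_dataset(
    n_milestones: int = 5,
    n_cells: int = 200,
    n_genes: int = 300,
    markers_per_branch: int = 20,
    effect_size: float = 2.0,
    seed: int = 0,
    dispersion: float = 0.5,
    library_cv: float = 0.3,
) -> tuple[TrajectoryModel, ExpressionMatrix, list[GeneSignature]]:
    """Generate a random branching trajectory with branch-marker ramps.

    Cells are placed uniformly on the edges of a random tree; each edge
    gets a disjoint set of marker genes whose log mean ramps linearly with
    the cell's progress along that edge (up to ``effect_size`` log-units).
    Returns the trajectory, the raw count matrix and one ground-truth
    signature per branch.
    """
    rng = np.random.default_rng(seed)
    edges = _random_tree(rng, n_milestones)
    milestones = [f"M{i}" for i in range(n_milestones)]
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    cell_ids = [f"C{j:05d}" for j in range(n_cells)]

    n_branches = len(edges)
    if markers_per_branch * n_branches > n_genes:
        raise ValueError("not enough genes for the requested branch markers")
    edge_choice = rng.integers(0, n_branches, size=n_cells)
    progress = rng.uniform(0.0, 1.0, size=n_cells)
    cell_edges = [(edges[e][0], edges[e][1]) for e in edge_choice]

    base = rng.lognormal(mean=-0.5, sigma=1.0, size=n_genes)
    log_mean = np.log(base)[:, None] + np.zeros((1, n_cells))
    signatures = []
    for b in range(n_branches):
        genes = np.arange(b * markers_per_branch, (b + 1) * markers_per_branch)
        on_branch = edge_choice == b
        ramp = np.where(on_branch, effect_size * progress, 0.0)
        log_mean[np.ix_(genes, np.arange(n_cells))] += ramp[None, :]
        signatures.append(
            GeneSignature(
                f"branch_{edges[b][0]}_{edges[b][1]}",
                frozenset(gene_ids[g] for g in genes),
            )
        )

    sigma_lib = np.sqrt(np.log1p(library_cv**2))
    lib = rng.lognormal(-0.5 * sigma_lib**2, sigma_lib, size=n_cells)
    shape = 1.0 / dispersion
    mean = np.exp(log_mean) * lib[None, :]
    lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
    counts = rng.poisson(lam).astype(float)

    traj = TrajectoryModel(
        milestones=milestones,
        edges=edges,
        cell_ids=cell_ids,
        cell_edges=cell_edges,
        progress=progress,
    )
    return traj, ExpressionMatrix(counts, gene_ids, cell_ids), signatures
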