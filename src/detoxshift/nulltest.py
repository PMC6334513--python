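"""Expression-structure analyses over species x plant mean profiles.

Covers the clustering side of the study: per-gene standardization of mean
expression profiles, Pearson-dissimilarity complete-linkage clustering of the
24 species x plant columns, the success criterion for clustering by the
host-performance bipartition, the random-gene-subset permutation null, PCA on
the correlation matrix, and per-gene two-factor variance partitioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierclust import Dendrogram, hierarchical_cluster
from .types import (
    ExpressionMatrix,
    PerformanceGrouping,
    SampleDesign,
    ValidationError,
    cell_label,
    split_cell_label,
)

log = logging.getLogger("detoxshift")

__all__ = [
    "mean_profiles",
    "standardize_per_gene",
    "pearson_dissimilarity",
    "profile_dendrogram",
    "bipartition_success",
    "NullTestResult",
    "random_subset_null",
    "pca_correlation",
    "variance_partition",
]


def mean_profiles(expr: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Mean expression per (species, plant) cell; genes x cells."""
    cells = design.cells()
    cols = {}
    for species, plant in cells:
        samples = design.cell_samples(species, plant)
        if not samples:
            raise ValidationError(f"empty design cell ({species}, {plant})")
        cols[cell_label(species, plant)] = expr.values[samples].mean(axis=1)
    return pd.DataFrame(cols)


def standardize_per_gene(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each gene row (sample sd, n-1); returns (matrix, flat_genes).

    Zero-variance rows are set to all-zeros and reported in the second
    element rather than producing NaNs.
    """
    if profiles.shape[1] < 2:
        raise ValidationError("need at least 2 columns to standardize")
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    return (
        pd.DataFrame(z, index=profiles.index, columns=profiles.columns),
        profiles.index[flat],
    )


def pearson_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between columns; range [0, 2], zero diagonal."""
    if profiles.shape[1] < 2 or profiles.shape[0] < 2:
        raise ValidationError("need >=2 columns and >=2 genes")
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = profiles.columns[np.argwhere(sd == 0)[0][0]]
        raise ValidationError(f"zero-variance column {bad!r}: correlation undefined")
    r = np.corrcoef(arr, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


def profile_dendrogram(
    expr: ExpressionMatrix, design: SampleDesign, linkage: str = "complete"
) -> Dendrogram:
    """mean profiles -> per-gene z-scores -> Pearson dissimilarity -> tree."""
    profiles = mean_profiles(expr, design)
    z, _ = standardize_per_gene(profiles)
    keep = z.to_numpy().std(axis=1) > 0
    return hierarchical_cluster(pearson_dissimilarity(z.loc[keep]), linkage=linkage)


def bipartition_success(
    dendrogram: Dendrogram, grouping: PerformanceGrouping
) -> bool:
    """Does the profile tree cluster species by their performance groups?

    TRUE iff (i) every species' plant columns form a contiguous subtree and
    (ii) the top split of the tree separates the species exactly into the
    grouping's high/low sets.  Accepts dendrograms over species x plant cell
    labels or over bare species labels (6-species-mean mode).
    """
    leaves = dendrogram.root.leaves()
    species_of_leaf = {}
    for leaf in leaves:
        if ":" in leaf:
            sp, _ = split_cell_label(leaf)
        else:
            sp = leaf
        species_of_leaf[leaf] = sp
    tree_species = set(species_of_leaf.values())
    missing = grouping.species - tree_species
    if missing:
        raise ValidationError(f"grouping species not in dendrogram: {sorted(missing)}")

    leaf_sets = dendrogram.leaf_sets()
    for sp in tree_species:
        cell_set = frozenset(l for l, s in species_of_leaf.items() if s == sp)
        if cell_set not in leaf_sets:
            return False
    top = dendrogram.root.children
    if len(top) != 2:
        return False
    side_species = [
        frozenset(species_of_leaf[l] for l in child.leaves()) for child in top
    ]
    return {frozenset(grouping.high), frozenset(grouping.low)} == set(side_species)


@dataclass(frozen=True)
class NullTestResult:
    """Outcome of the random-gene-subset clustering null."""

    n_trials: int
    subset_size: int
    n_success: int
    seed: int
    success_criterion: str = "species-contiguity+performance-bipartition"

    @property
    def empirical_p(self) -> float:
        # (k+1)/(n+1) convention: avoids zero p from finite trials
        return (self.n_success + 1) / (self.n_trials + 1)

    def to_jsonable(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "subset_size": self.subset_size,
            "n_success": self.n_success,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "success_criterion": self.success_criterion,
        }


def random_subset_null(
    expr: ExpressionMatrix,
    design: SampleDesign,
    grouping: PerformanceGrouping,
    subset_size: int = 266,
    n_trials: int = 500,
    seed: int = 0,
    linkage: str = "complete",
) -> NullTestResult:
    """Clustering permutation null over random gene subsets.

    Each trial samples ``subset_size`` genes without replacement from the
    supplied expression pool, builds the standardized-profile dendrogram of
    its species x plant columns, and records whether it clusters the species
    by the performance grouping.  Mean profiles and per-gene z-scores are
    gene-wise operations, so they are computed once for the whole pool and
    subset per trial.
    """
    n_pool = expr.values.shape[0]
    if n_pool < subset_size:
        raise ValidationError(
            f"gene pool ({n_pool}) smaller than subset size ({subset_size})"
        )
    profiles = mean_profiles(expr, design)
    z, _ = standardize_per_gene(profiles)
    zarr = z.to_numpy()
    informative = zarr.std(axis=1) > 0
    rng = np.random.default_rng(seed)
    n_success = 0
    for trial in range(n_trials):
        idx = rng.choice(n_pool, size=subset_size, replace=False)
        idx = idx[informative[idx]]
        sub = z.iloc[idx]
        dend = hierarchical_cluster(pearson_dissimilarity(sub), linkage=linkage)
        if bipartition_success(dend, grouping):
            n_success += 1
    log.info(
        "random_subset_null: %d/%d trials clustered by the performance grouping",
        n_success, n_trials,
    )
    return NullTestResult(
        n_trials=n_trials, subset_size=subset_size, n_success=n_success, seed=seed
    )


def pca_correlation(
    expr: ExpressionMatrix, design: SampleDesign | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples using the correlation (standardized-gene) method.

    Genes are z-scored across samples (zero-variance genes dropped with a
    warning); the eigendecomposition of the resulting gene-gene correlation
    structure is obtained through the SVD of the standardized data.  Returns
    (sample scores, explained-variance fractions); fractions sum to 1 and the
    eigenvectors implied by the SVD have unit norm.
    """
    arr = expr.values.to_numpy(dtype=float).T  # samples x genes
    if arr.shape[0] < 2:
        raise ValidationError("need at least 2 samples for PCA")
    sd = arr.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("pca_correlation: dropped %d zero-variance genes", dropped)
    zs = (arr[:, keep] - arr[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(zs, full_matrices=False)
    ev = s**2
    fractions = ev / ev.sum()
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=expr.values.columns, columns=cols),
        fractions,
    )


def variance_partition(
    expr: ExpressionMatrix, design: SampleDesign
) -> pd.DataFrame:
    """Per-gene two-factor (species x plant) sum-of-squares fractions.

    Requires a balanced design with replicates.  Returns a genes x
    {species, plant, interaction, residual} table of SS fractions summing to
    1 per gene (genes with zero total SS get NaN fractions).
    """
    t = design.table
    species = design.species
    plants = design.plants
    reps = None
    for s in species:
        for p in plants:
            n = len(design.cell_samples(s, p))
            if reps is None:
                reps = n
            elif n != reps:
                raise ValidationError(
                    "variance partition requires a balanced design "
                    f"(cell ({s}, {p}) has {n} replicates, expected {reps})"
                )
    if reps is None or reps < 2:
        raise ValidationError("variance partition requires replicated cells")

    arr = expr.values[design.sample_ids].to_numpy(dtype=float)
    sp_idx = pd.Categorical(t["species"], categories=species).codes
    pl_idx = pd.Categorical(t["plant"], categories=plants).codes
    n_sp, n_pl = len(species), len(plants)
    n = arr.shape[1]
    grand = arr.mean(axis=1, keepdims=True)

    cell_means = np.zeros((arr.shape[0], n_sp, n_pl))
    for i in range(n_sp):
        for j in range(n_pl):
            cols = (sp_idx == i) & (pl_idx == j)
            cell_means[:, i, j] = arr[:, cols].mean(axis=1)
    sp_means = cell_means.mean(axis=2)
    pl_means = cell_means.mean(axis=1)

    ss_species = reps * n_pl * ((sp_means - grand) ** 2).sum(axis=1)
    ss_plant = reps * n_sp * ((pl_means - grand) ** 2).sum(axis=1)
    inter = (
        cell_means
        - sp_means[:, :, None]
        - pl_means[:, None, :]
        + grand[:, :, None]
    )
    ss_inter = reps * (inter**2).sum(axis=(1, 2))
    ss_total = ((arr - grand) ** 2).sum(axis=1)
    ss_resid = ss_total - ss_species - ss_plant - ss_inter
    ss_resid = np.maximum(ss_resid, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        out = pd.DataFrame(
            {
                "species": ss_species / ss_total,
                "plant": ss_plant / ss_total,
                "interaction": ss_inter / ss_total,
                "residual": ss_resid / ss_total,
            },
            index=expr.values.index,
        )
    return out
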