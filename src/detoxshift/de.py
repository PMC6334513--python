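"""Count filtering, normalization and negative-binomial differential
expression.

This is a self-contained NB stand-in for the external DE engines commonly
used on bulk RNA-seq counts: median-of-ratios size factors, per-gene
method-of-moments dispersion (Var = mu + alpha * mu^2), a delta-method Wald
test on the log2 fold change of normalized cell means, and Benjamini-Hochberg
adjustment across all retained genes.  The analysis logic layered on top
(thresholds, contrasts, classification) is the point; numerical parity with
any particular engine is not claimed.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, ExpressionMatrix, SampleDesign, ValidationError, cell_label

log = logging.getLogger("detoxshift")

__all__ = [
    "filter_low_counts",
    "size_factors_median_ratio",
    "normalize_counts",
    "estimate_dispersion",
    "nb_wald_test",
    "adjust_bh",
    "regularized_log",
    "call_de",
]

DISPERSION_FLOOR = 1e-8
PSEUDO_MEAN = 0.5  # pseudo-mean inside fold changes, avoids division by zero
LOG2 = math.log(2.0)


def filter_low_counts(
    counts: CountMatrix, min_reads: int = 10, sample_fraction: float = 0.04
) -> CountMatrix:
    """Drop genes without >= ``min_reads`` in >= ceil(fraction * n) samples."""
    if min_reads < 0:
        raise ValidationError("min_reads must be >= 0")
    if not 0 < sample_fraction <= 1:
        raise ValidationError("sample_fraction must be in (0, 1]")
    required = math.ceil(sample_fraction * counts.n_samples)
    ok = (counts.values.to_numpy() >= min_reads).sum(axis=1) >= required
    kept = counts.values.loc[ok]
    log.info(
        "filter_low_counts: kept %d of %d genes (>=%d reads in >=%d of %d samples)",
        int(ok.sum()), counts.n_genes, min_reads, required, counts.n_samples,
    )
    if kept.empty:
        warnings.warn("all genes filtered out", stacklevel=2)
    return CountMatrix(kept, counts.design)


def size_factors_median_ratio(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the standard RNA-seq convention).

    factor_j = median over reference genes g of count_gj / geomean_g, where
    the reference excludes genes with any zero count.
    """
    arr = counts.values.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError(
            "no gene with all-positive counts; add a pseudocount before normalizing"
        )
    ref = arr[allpos]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    if (size_factors <= 0).any():
        raise ValidationError("size factors must be positive")
    return counts.values / size_factors.loc[counts.sample_ids].to_numpy()


def estimate_dispersion(
    counts: CountMatrix, size_factors: pd.Series, design: SampleDesign
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, pooled across cells.

    Within each (species, plant) cell the sample variance and mean of the
    normalized counts are computed; pooling across cells gives
    alpha = max(floor, (s^2 - mu) / mu^2).
    """
    norm = normalize_counts(counts, size_factors)
    cells = design.cells()
    cells_with_reps = [c for c in cells if len(design.cell_samples(*c)) >= 2]
    if not cells_with_reps:
        raise ValidationError(
            "dispersion estimation requires >=2 replicates in at least one cell"
        )
    var_sum = np.zeros(counts.n_genes)
    mean_sum = np.zeros(counts.n_genes)
    df_sum = 0
    for species, plant in cells_with_reps:
        cols = design.cell_samples(species, plant)
        block = norm[cols].to_numpy()
        var_sum += block.var(axis=1, ddof=1) * (len(cols) - 1)
        mean_sum += block.mean(axis=1)
        df_sum += len(cols) - 1
    pooled_var = var_sum / df_sum
    mean_bar = mean_sum / len(cells_with_reps)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean_bar) / np.square(mean_bar)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def nb_wald_test(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[tuple[str, str], tuple[str, str]],
) -> pd.DataFrame:
    """Wald test of one condition-cell contrast for every gene.

    ``contrast = ((species_ref, plant_ref), (species_test, plant_test))``;
    the reported log2 fold change is test over reference:
    ``log2((mean_test + c) / (mean_ref + c))`` on normalized counts with
    pseudo-mean ``c = 0.5``.  The standard error comes from the delta method
    applied to the NB variance ``mu + alpha mu^2`` of each cell mean, and the
    p-value is a two-sided normal tail.

    Returns a DataFrame indexed by gene with columns ``log2fc, p`` (adjusted
    p-values are added separately by :func:`adjust_bh` across contrasts).
    """
    (ref_cell, test_cell) = contrast
    design = counts.design
    ref_cols = design.cell_samples(*ref_cell)
    test_cols = design.cell_samples(*test_cell)
    if not ref_cols or not test_cols:
        empty = ref_cell if not ref_cols else test_cell
        raise ValidationError(f"contrast cell {empty} has no samples")
    norm = normalize_counts(counts, size_factors)
    alpha = dispersions.loc[counts.gene_ids].to_numpy(dtype=float)
    if (alpha <= 0).any():
        raise ValidationError("dispersions must be positive")

    def cell_stats(cols: list[str]) -> tuple[np.ndarray, np.ndarray]:
        block = norm[cols]
        m = block.mean(axis=1).to_numpy() + PSEUDO_MEAN
        inv_s = (1.0 / size_factors.loc[cols].to_numpy()).sum()
        n = len(cols)
        # Var(mean of k_j/s_j) with k_j ~ NB(s_j q, alpha), q plugged in as m
        var = m * inv_s / n**2 + alpha * np.square(m) / n
        return m, var

    m_ref, var_ref = cell_stats(ref_cols)
    m_test, var_test = cell_stats(test_cols)
    log2fc = np.log2(m_test) - np.log2(m_ref)
    se = np.sqrt(var_test / np.square(m_test) + var_ref / np.square(m_ref)) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    out = pd.DataFrame(
        {
            "ref": cell_label(*ref_cell),
            "test": cell_label(*test_cell),
            "log2fc": log2fc,
            "p": p,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return out


def adjust_bh(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to BH adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def regularized_log(
    counts: CountMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Shifted log2 of normalized counts: log2(count/factor + pseudocount).

    A documented stand-in for regularized-log transforms: it preserves the
    log2 scale and monotonicity but performs no shrinkage of low-count genes.
    """
    norm = normalize_counts(counts, size_factors)
    return ExpressionMatrix(np.log2(norm + pseudocount))


def call_de(
    results: pd.DataFrame, lfc_threshold: float, padj_threshold: float = 0.05
) -> pd.DataFrame:
    """Apply fold-change and FDR thresholds; tag calls up/down.

    ``results`` must carry ``log2fc`` and ``padj`` columns.  A gene is called
    iff |log2fc| >= lfc_threshold and padj <= padj_threshold.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    sig = (results["log2fc"].abs() >= lfc_threshold) & (
        results["padj"] <= padj_threshold
    )
    out = results.loc[sig].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out
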