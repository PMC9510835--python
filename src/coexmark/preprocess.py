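"""Missing-value imputation, batch location adjustment, variance filter.

The pipeline order is fixed: impute → adjust batches → variance filter.
Batch adjustment is a per-gene location (mean-centering) adjustment, not
empirical-Bayes ComBat: each batch's mean is shifted to the gene's grand
mean, which removes additive batch offsets exactly and is what the
synthetic generator plants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

__all__ = ["PreprocessReport", "knn_impute", "adjust_batches", "variance_filter", "run"]


@dataclass
class PreprocessReport:
    n_imputed_cells: int = 0
    n_genes_before: int = 0
    n_genes_after: int = 0
    variance_quantile_used: float = 1.0
    batch_adjusted: bool = False


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing cells from the ``k`` nearest genes (classic KNNimpute).

    Neighbors are genes, compared by Euclidean distance over the samples
    where both genes are observed; a missing cell becomes the mean of its
    gene's k nearest neighbors that are observed at that sample. Observed
    cells are never altered, so the operation is idempotent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.to_numpy(dtype=float)
    if not np.isnan(values).any():
        return matrix
    all_missing = matrix.index[np.isnan(values).all(axis=1)].tolist()
    if all_missing:
        raise ValueError(f"genes with all values missing: {all_missing}")
    few = matrix.index[(~np.isnan(values)).sum(axis=1) < 2].tolist()
    if few:
        raise ValueError(f"genes with fewer than 2 observed values: {few}")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values)  # genes are rows: neighbors are genes
    observed = ~np.isnan(values)
    filled[observed] = values[observed]
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def adjust_batches(matrix: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Shift every batch's per-gene mean to the gene's grand mean.

    With a single batch the input is returned unchanged (with a log notice).
    """
    if "batch" not in phenotypes.columns:
        raise ValueError("phenotype table has no 'batch' column")
    batches = phenotypes.loc[matrix.columns, "batch"]
    if batches.isna().any():
        raise ValueError("batch labels missing for some samples")
    unique = batches.unique()
    if len(unique) < 2:
        logger.info("single batch: no adjustment applied")
        return matrix
    values = matrix.to_numpy(dtype=float).copy()
    grand = np.nanmean(values, axis=1, keepdims=True)
    for b in unique:
        cols = np.flatnonzero((batches == b).to_numpy())
        batch_mean = np.nanmean(values[:, cols], axis=1, keepdims=True)
        values[:, cols] += grand - batch_mean
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def variance_filter(matrix: pd.DataFrame, top_fraction: float = 0.25) -> pd.DataFrame:
    """Keep the ceil(top_fraction * n_genes) highest-variance genes.

    Variance uses denominator n−1; ties at the boundary break by gene id
    (lexicographic) for determinism. Row order of the kept genes follows
    the input matrix.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if matrix.shape[1] < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    n_keep = math.ceil(top_fraction * matrix.shape[0])
    variances = matrix.var(axis=1, ddof=1, skipna=True)
    order = sorted(matrix.index, key=lambda g: (-variances[g], g))
    keep = set(order[:n_keep])
    return matrix.loc[[g for g in matrix.index if g in keep]]


def run(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    k: int = 10,
    top_fraction: float = 0.25,
    batch_adjust: bool = True,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Impute → (optionally) adjust batches → variance filter."""
    report = PreprocessReport(
        n_genes_before=matrix.shape[0], variance_quantile_used=top_fraction
    )
    n_missing = int(matrix.isna().to_numpy().sum())
    if n_missing:
        matrix = knn_impute(matrix, k=k)
        report.n_imputed_cells = n_missing
    if batch_adjust and "batch" in phenotypes.columns:
        n_batches = phenotypes.loc[matrix.columns, "batch"].nunique()
        if n_batches > 1:
            matrix = adjust_batches(matrix, phenotypes)
            report.batch_adjusted = True
    matrix = variance_filter(matrix, top_fraction=top_fraction)
    report.n_genes_after = matrix.shape[0]
    return matrix, report
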