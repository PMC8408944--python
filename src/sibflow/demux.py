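"""Mother-of-origin assignment from per-cell SNP dosages.

Pairwise Ajk relatedness (allele-frequency-standardized genotype covariance
over SNPs non-missing in both cells), agglomerative clustering of the derived
distance matrix cut at the known number of adults, and within-cluster outlier
filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import core_expr

__all__ = [
    "GenotypeMatrix",
    "RelatednessMatrix",
    "ajk_relatedness",
    "cluster_mothers",
    "flag_outliers",
    "attach_and_regress",
]


@dataclass
class GenotypeMatrix:
    """Dosages (cells x SNPs) in {0, 1, 2}, NaN for missing calls."""

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.dosages.shape[1] == 0:
            raise ValueError("no SNPs: relatedness is undefined")
        if self.dosages.shape[0] < 2:
            raise ValueError("need at least 2 cells")

    @property
    def cells(self) -> pd.Index:
        return self.dosages.index

    def allele_frequencies(self) -> pd.Series:
        """In-sample alternate-allele frequency per SNP over non-missing calls."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0


@dataclass
class RelatednessMatrix:
    values: pd.DataFrame  # cells x cells, symmetric, NaN diagonal
    pair_counts: pd.DataFrame  # SNPs used per pair

    @property
    def cells(self) -> pd.Index:
        return self.values.index


def ajk_relatedness(
    G: GenotypeMatrix | pd.DataFrame,
    allele_freq: Optional[pd.Series] = None,
    min_calls: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> RelatednessMatrix:
    """Unadjusted Ajk relatedness between every pair of cells.

    For cells j != k,
        A_jk = (1/N_jk) * sum_i (g_ij - 2 p_i)(g_ik - 2 p_i) / (2 p_i (1 - p_i))
    over SNPs i non-missing in both cells.  SNPs with fewer than ``min_calls``
    non-missing calls or allele frequency outside ``maf_range`` are excluded.
    ``allele_freq`` overrides the in-sample frequencies (and skips the filter).
    """
    if isinstance(G, pd.DataFrame):
        G = GenotypeMatrix(G)
    dos = G.dosages
    if allele_freq is not None:
        p = allele_freq.reindex(dos.columns).to_numpy(dtype=float)
        usable = np.isfinite(p) & (p > 0) & (p < 1)
    else:
        p = G.allele_frequencies().to_numpy(dtype=float)
        n_called = dos.notna().sum(axis=0).to_numpy()
        usable = (
            (n_called >= min_calls)
            & np.isfinite(p)
            & (p >= maf_range[0])
            & (p <= maf_range[1])
        )
    if not usable.any():
        raise ValueError("no usable SNPs after filtering")
    X = dos.to_numpy(dtype=float)[:, usable]
    p = p[usable]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Y = (X - 2.0 * p) / denom
    M = np.isfinite(Y)
    Y0 = np.where(M, Y, 0.0)
    num = Y0 @ Y0.T
    N = M.astype(float) @ M.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = num / N
    if (N[~np.eye(len(A), dtype=bool)] == 0).any():
        warnings.warn("cell pair(s) share no usable SNPs; entries set missing")
    A[N == 0] = np.nan
    np.fill_diagonal(A, np.nan)
    cells = G.cells
    return RelatednessMatrix(
        values=pd.DataFrame(A, index=cells, columns=cells),
        pair_counts=pd.DataFrame(N.astype(int), index=cells, columns=cells),
    )


def _distance_matrix(R: RelatednessMatrix) -> np.ndarray:
    A = R.values.to_numpy(dtype=float).copy()
    off = ~np.eye(len(A), dtype=bool)
    if np.isnan(A[off]).any():
        warnings.warn("missing relatedness entries imputed to column medians")
        med = np.nanmedian(np.where(off, A, np.nan), axis=0)
        ii, jj = np.where(np.isnan(A) & off)
        A[ii, jj] = med[jj]
        A = (A + A.T) / 2.0
    amax = np.nanmax(A[off])
    D = amax - A
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    return D


def cluster_mothers(
    R: RelatednessMatrix, k_mothers: int, method: str = "average"
) -> tuple[pd.Series, np.ndarray]:
    """Cut the relatedness-derived dendrogram into exactly ``k_mothers``
    clusters.  Distance is max(A) - A_jk (Ajk is unbounded above, so 1 - A
    could go negative).  Returns (labels, scipy linkage matrix)."""
    n = len(R.cells)
    if k_mothers < 2:
        raise ValueError("k_mothers must be >= 2")
    if k_mothers > n:
        raise ValueError(f"k_mothers={k_mothers} exceeds number of cells ({n})")
    D = _distance_matrix(R)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    raw = hierarchy.fcluster(Z, t=k_mothers, criterion="maxclust")
    labels = pd.Series(
        [f"mother{int(x)}" for x in raw], index=R.cells, name="mother"
    )
    return labels, Z


def flag_outliers(
    R: RelatednessMatrix,
    labels: pd.Series,
    quantile: float = 0.01,
) -> pd.DataFrame:
    """Flag cells whose mean within-cluster relatedness falls below the
    cluster's ``quantile`` threshold.

    Clusters of fewer than 3 members are marked for review, not auto-dropped.
    Returns a frame (mother, mean_within_relatedness, kept, review).
    """
    labels = labels.reindex(R.cells)
    A = R.values
    rows = []
    for mother, members in labels.groupby(labels).groups.items():
        members = list(members)
        sub = A.loc[members, members]
        means = sub.mean(axis=1, skipna=True)  # diagonal is NaN -> excluded
        if len(members) < 3:
            for c in members:
                rows.append((c, mother, means[c], True, True))
            continue
        thr = means.quantile(quantile)
        for c in members:
            rows.append((c, mother, means[c], bool(means[c] >= thr), False))
    out = pd.DataFrame(
        rows, columns=["cell", "mother", "mean_within_relatedness", "kept", "review"]
    ).set_index("cell")
    return out.loc[R.cells]


def attach_and_regress(
    cm: core_expr.CountMatrix, labels: pd.Series
) -> tuple[core_expr.CountMatrix, pd.DataFrame]:
    """Attach mother labels to the count matrix and return it together with
    mother-batch-corrected normalized expression."""
    missing = [c for c in cm.counts.columns if c not in labels.index or pd.isna(labels.get(c))]
    if missing:
        raise ValueError(f"retained cells without a mother label: {missing}")
    cells = cm.cells.copy()
    cells["mother"] = labels.reindex(cells.index)
    cm2 = core_expr.CountMatrix(counts=cm.counts, cells=cells, genes=cm.genes)
    expr = core_expr.normalize(cm2, batch=cells["mother"])
    return cm2, expr
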