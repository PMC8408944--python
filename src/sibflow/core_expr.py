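"""Expression-matrix backbone.

Cell filtering by per-stage detected-gene thresholds, depth normalization with
per-gene batch-mean equalization, pseudo-bulk averaging, Wilcoxon rank-sum
differential expression, PCA embedding with a deterministic sign convention,
and a nearest-centroid label-transfer classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "FilterConfig",
    "DEResult",
    "EmbedConfig",
    "Embedding",
    "filter_cells",
    "normalize",
    "pseudobulk",
    "log2_fold_change",
    "wilcoxon_de",
    "pca_embed",
    "transfer_labels",
]

#: groups with both sizes at or below this use the exact rank-sum null
EXACT_WILCOXON_MAX_N = 8


@dataclass
class CountMatrix:
    """UMI counts (genes x cells) plus per-cell and per-gene metadata.

    ``cells`` is indexed by cell barcode and may carry ``stage``,
    ``treatment``, ``mother`` and ``state`` columns; ``genes`` is indexed by
    gene id and may carry an ``is_tf`` flag.
    """

    counts: pd.DataFrame
    cells: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate cell identifiers in count matrix")
        if not self.counts.columns.equals(self.cells.index):
            raise ValueError("cell metadata index does not match count columns")
        if not self.counts.index.equals(self.genes.index):
            raise ValueError("gene metadata index does not match count rows")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        barcodes = list(barcodes)
        return CountMatrix(
            counts=self.counts.loc[:, barcodes],
            cells=self.cells.loc[barcodes],
            genes=self.genes,
        )


@dataclass
class FilterConfig:
    """Per-stage minimum detected-gene thresholds, e.g.
    ``{"64-cell": 1750, "112-cell": 2500, "mid-gastrula": 1500}``."""

    min_genes: Mapping[str, int]

    def __post_init__(self) -> None:
        for stage, thr in self.min_genes.items():
            if thr <= 0:
                raise ValueError(f"threshold for stage {stage!r} must be positive")


@dataclass
class DEResult:
    gene: str
    log2fc: float
    p_value: float
    pct_group1: float
    pct_group2: float


@dataclass
class EmbedConfig:
    n_pcs: int = 25
    scale_genes: bool = False


@dataclass
class Embedding:
    """PCA embedding plus the projection needed to map new cells into it."""

    coords: pd.DataFrame  # cells x PCs
    components: np.ndarray  # n_pcs x n_genes
    explained_variance: np.ndarray
    gene_mean: np.ndarray
    gene_scale: np.ndarray
    genes: pd.Index

    def project(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Project genes-x-cells expression into this embedding's space."""
        missing = self.genes.difference(expr.index)
        if len(missing) == len(self.genes):
            raise ValueError("no shared genes between embedding and query")
        X = expr.reindex(self.genes).fillna(0.0).to_numpy().T
        Z = ((X - self.gene_mean) / self.gene_scale) @ self.components.T
        cols = [f"PC{i + 1}" for i in range(self.components.shape[0])]
        return pd.DataFrame(Z, index=expr.columns, columns=cols)


def filter_cells(cm: CountMatrix, cfg: FilterConfig) -> CountMatrix:
    """Drop cells whose detected-gene count is below the threshold for their
    stage.  Cell order is preserved."""
    if "stage" not in cm.cells.columns:
        raise ValueError("cell metadata lacks a 'stage' column")
    stages = cm.cells["stage"]
    unknown = set(stages.unique()) - set(cfg.min_genes)
    if unknown:
        raise ValueError(f"no filter threshold for stage(s): {sorted(unknown)}")
    detected = (cm.counts.to_numpy() > 0).sum(axis=0)
    thresholds = stages.map(cfg.min_genes).to_numpy()
    keep = detected >= thresholds
    return cm.subset_cells(cm.counts.columns[keep])


def normalize(
    cm: CountMatrix | pd.DataFrame,
    batch: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Depth-normalize to the median total count, log1p, and optionally
    equalize per-gene within-batch means to the per-gene global mean.

    Batches with a single cell are skipped (warning); their cells keep the
    depth-scaled log values.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    depths = counts.sum(axis=0).to_numpy(dtype=float)
    if (depths == 0).any():
        raise ValueError("cell(s) with zero total counts; filter first")
    target = float(np.median(depths))
    expr = np.log1p(counts.to_numpy(dtype=float) * (target / depths))
    expr = pd.DataFrame(expr, index=counts.index, columns=counts.columns)
    if batch is not None:
        batch = batch.reindex(counts.columns)
        if batch.isna().any():
            raise ValueError("batch label missing for some cells")
        global_mean = expr.mean(axis=1)
        for name, cols in expr.columns.groupby(batch.to_numpy()).items():
            if len(cols) < 2:
                warnings.warn(
                    f"batch {name!r} has a single cell; batch term skipped"
                )
                continue
            shift = global_mean - expr[cols].mean(axis=1)
            expr.loc[:, cols] = expr.loc[:, cols].add(shift, axis=0)
    return expr


def pseudobulk(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-state arithmetic mean of expression: returns state x gene."""
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every cell must carry a state label")
    empty = set(labels.unique()) - set(labels.dropna().unique())
    if empty:
        warnings.warn(f"empty state(s) excluded: {sorted(empty)}")
    return expr.T.groupby(labels).mean()


def _mean_expm1(expr: pd.DataFrame, cells: Sequence[str]) -> np.ndarray:
    return np.expm1(expr.loc[:, list(cells)].to_numpy()).mean(axis=1)


def log2_fold_change(
    expr: pd.DataFrame, cells_a: Sequence[str], cells_b: Sequence[str]
) -> pd.Series:
    """Seurat-style pseudocount-1 log2 fold change on de-logged group means."""
    ma = _mean_expm1(expr, cells_a)
    mb = _mean_expm1(expr, cells_b)
    return pd.Series(np.log2((ma + 1.0) / (mb + 1.0)), index=expr.index)


def _exact_ranksum_p(values: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p by enumerating all group-A assignments.

    Handles ties because the enumeration is over the observed (tied) ranks.
    """
    n = len(values)
    ranks = stats.rankdata(values)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            count += 1
    return count / total


def _asymptotic_ranksum_p(
    pooled: np.ndarray, n1: int, continuity: bool = True
) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p-values.

    ``pooled`` is genes x (n1 + n2) with group A in the first n1 columns.
    Tie correction per gene; sigma == 0 (all values tied) gives p = 1.
    """
    n_genes, n = pooled.shape
    n2 = n - n1
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie term sum(t^3 - t) per gene from sorted rows
    srt = np.sort(pooled, axis=1)
    tie_sum = np.zeros(n_genes)
    for g in range(n_genes):
        _, counts = np.unique(srt[g], return_counts=True)
        tie_sum[g] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    sigma = np.sqrt(var)
    dev = np.abs(w - mu)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, dev / sigma, 0.0)
    p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    p[sigma == 0] = 1.0
    return p


def wilcoxon_de(
    expr: pd.DataFrame,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    min_lfc: float = 0.0,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two cell groups.

    Exact enumeration when both groups have <= 8 cells, otherwise the normal
    approximation with tie and continuity correction.  Returns a per-gene
    frame (gene, log2fc, p_value, pct_group1, pct_group2, significant) where
    ``significant`` applies the (alpha, min_lfc) reporting rule.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if not cells_a or not cells_b:
        raise ValueError("both groups must be nonempty")
    A = expr.loc[:, cells_a].to_numpy(dtype=float)
    B = expr.loc[:, cells_b].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    pooled = np.concatenate([A, B], axis=1)
    if n1 <= EXACT_WILCOXON_MAX_N and n2 <= EXACT_WILCOXON_MAX_N:
        p = np.array([_exact_ranksum_p(row, n1) for row in pooled])
    else:
        p = _asymptotic_ranksum_p(pooled, n1)
    lfc = log2_fold_change(expr, cells_a, cells_b)
    res = pd.DataFrame(
        {
            "gene": expr.index,
            "log2fc": lfc.to_numpy(),
            "p_value": p,
            "pct_group1": (A > 0).mean(axis=1),
            "pct_group2": (B > 0).mean(axis=1),
        }
    ).set_index("gene", drop=False)
    res.index.name = None
    res["significant"] = (res["p_value"] < alpha) & (res["log2fc"].abs() >= min_lfc)
    return res


def pca_embed(expr: pd.DataFrame, cfg: EmbedConfig) -> Embedding:
    """PCA on cells-x-genes (genes centered, optionally unit-scaled).

    Sign convention: per component, the loading with the largest magnitude is
    made positive, so embeddings are reproducible across runs and platforms.
    """
    genes = expr.index
    X = expr.to_numpy(dtype=float).T  # cells x genes
    n_cells, n_genes = X.shape
    max_pcs = min(n_genes, n_cells) - 1
    if cfg.n_pcs < 1 or cfg.n_pcs > max_pcs:
        raise ValueError(f"n_pcs must be in [1, {max_pcs}]")
    mean = X.mean(axis=0)
    scale = np.ones(n_genes)
    if cfg.scale_genes:
        sd = X.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene(s) dropped before scaling"
            )
            keep = ~constant
            genes = genes[keep]
            X, mean, sd = X[:, keep], mean[keep], sd[keep]
        scale = sd
    Xc = (X - mean) / scale
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = cfg.n_pcs
    comps = Vt[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            U[:, i] = -U[:, i]
    coords = U[:, :k] * S[:k]
    ev = (S[:k] ** 2) / (n_cells - 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    return Embedding(
        coords=pd.DataFrame(coords, index=expr.columns, columns=cols),
        components=comps,
        explained_variance=ev,
        gene_mean=mean,
        gene_scale=np.asarray(scale, dtype=float),
        genes=pd.Index(genes),
    )


def transfer_labels(
    ref_expr: pd.DataFrame,
    ref_labels: pd.Series,
    query_expr: pd.DataFrame,
    cfg: Optional[EmbedConfig] = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Nearest-centroid label transfer in the reference PCA space.

    Confidence is the softmax of negative centroid distances.  Exact ties are
    broken deterministically toward the label earlier in sort order.
    """
    shared = ref_expr.index.intersection(query_expr.index)
    if len(shared) == 0:
        raise ValueError("reference and query share no genes")
    if cfg is None:
        cfg = EmbedConfig(n_pcs=min(10, min(ref_expr.shape) - 1, len(shared) - 1))
    emb = pca_embed(ref_expr.loc[shared], cfg)
    ref_labels = ref_labels.reindex(ref_expr.columns)
    centroids = emb.coords.groupby(ref_labels).mean().sort_index()
    qcoords = emb.project(query_expr.loc[shared])
    diffs = qcoords.to_numpy()[:, None, :] - centroids.to_numpy()[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=2))
    # argmin takes the first minimum -> earlier label in sorted order wins ties
    assign = centroids.index[np.argmin(dist, axis=1)]
    logits = -dist - (-dist).max(axis=1, keepdims=True)
    conf = np.exp(logits)
    conf /= conf.sum(axis=1, keepdims=True)
    labels = pd.Series(assign, index=query_expr.columns, name="label")
    confidence = pd.DataFrame(conf, index=query_expr.columns, columns=centroids.index)
    return labels, confidence
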