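"""Temporal expression-module ("wave") analysis.

Union of per-stage enriched genes, Ward clustering of pseudo-bulk temporal
profiles with k- or height-based cuts, and per-stage motif-enrichment time
courses with early/late epoch summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import motif as motif_mod

__all__ = [
    "WaveAssignment",
    "enriched_union",
    "wave_cluster",
    "tfbs_timecourse",
]


@dataclass
class WaveAssignment:
    waves: pd.Series  # gene -> wave id (1-based, ordered by peak stage)
    linkage: np.ndarray
    k: Optional[int]
    cut_height: Optional[float]


def enriched_union(
    de_by_stage: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    min_lfc: float = 0.3,
) -> list[str]:
    """Genes passing (p < alpha, log2FC >= min_lfc) at any stage."""
    genes: set[str] = set()
    for stage, de in de_by_stage.items():
        hit = de[(de["p_value"] < alpha) & (de["log2fc"] >= min_lfc)]
        genes.update(hit["gene"] if "gene" in hit.columns else hit.index)
    return sorted(genes)


def _scale_profiles(profiles: pd.DataFrame, scaling: str) -> pd.DataFrame:
    if scaling == "max":
        mx = profiles.max(axis=1)
        mx = mx.where(mx != 0, 1.0)
        return profiles.div(mx, axis=0)
    if scaling == "zscore":
        mu = profiles.mean(axis=1)
        sd = profiles.std(axis=1, ddof=0).where(lambda s: s != 0, 1.0)
        return profiles.sub(mu, axis=0).div(sd, axis=0)
    if scaling == "none":
        return profiles
    raise ValueError("scaling must be 'max', 'zscore' or 'none'")


def wave_cluster(
    profiles: pd.DataFrame,
    k: Optional[int] = 5,
    cut_height: Optional[float] = None,
    scaling: str = "max",
) -> WaveAssignment:
    """Ward-linkage clustering of gene x stage temporal profiles.

    Profiles are per-gene max-normalized by default.  Clusters are cut to
    ``k`` groups (default) or at ``cut_height``; wave ids are renumbered by
    the stage at which each wave's mean profile peaks, so labels are stable
    across runs.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    if k is not None and k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({profiles.shape[0]})")
    X = _scale_profiles(profiles, scaling)
    Z = hierarchy.linkage(pdist(X.to_numpy()), method="ward")
    if cut_height is not None:
        raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    else:
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assign = pd.Series(raw, index=profiles.index)
    # order waves by the peak stage of their mean scaled profile
    peak_stage = {
        w: int(np.argmax(X.loc[assign[assign == w].index].mean(axis=0)))
        for w in np.unique(raw)
    }
    order = sorted(peak_stage, key=lambda w: (peak_stage[w], w))
    remap = {w: i + 1 for i, w in enumerate(order)}
    waves = assign.map(remap).rename("wave")
    return WaveAssignment(waves=waves, linkage=Z, k=k, cut_height=cut_height)


def tfbs_timecourse(
    stage_sets: Mapping[str, tuple[Mapping[str, Mapping[str, str]], Mapping[str, Mapping[str, str]]]],
    pwms: Mapping[str, motif_mod.PWM],
    cfg: Optional[motif_mod.RegionConfig] = None,
    stage_order: Optional[Sequence[str]] = None,
    epoch_split: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combined enrichment z per PWM per stage, plus epoch averages.

    ``stage_sets[stage]`` is a (target, control) pair, each mapping
    representation name ('upstream', 'atac') to a sequence set.  Stages with
    an empty target or control yield NaN columns (flagged by the NaN).
    Returns (pwm x stage z matrix, pwm x {early, late} epoch means).
    """
    cfg = cfg or motif_mod.RegionConfig()
    stages = list(stage_order) if stage_order is not None else list(stage_sets)
    mat = pd.DataFrame(index=list(pwms), columns=stages, dtype=float)
    for stage in stages:
        target, control = stage_sets[stage]
        for name, pwm in pwms.items():
            zs = [
                motif_mod._set_zscore(
                    target.get(rep, {}), control.get(rep, {}), pwm, cfg
                )
                for rep in ("upstream", "atac")
            ]
            z, _ = motif_mod.combined_zscore(*zs)
            if z is None:
                warnings.warn(f"stage {stage!r}: z unavailable for {name}")
                mat.loc[name, stage] = np.nan
            else:
                mat.loc[name, stage] = z
    split = epoch_split if epoch_split is not None else len(stages) // 2
    epochs = pd.DataFrame(
        {
            "early": mat.iloc[:, :split].mean(axis=1),
            "late": mat.iloc[:, split:].mean(axis=1),
        }
    )
    return mat, epochs
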