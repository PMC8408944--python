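"""Lineage-tree analytics over cell-state bifurcations.

Covers the chi-square sensitivity score with descendant summation and
exclusion propagation, the five-way trio mechanism classifier with its
+/-0.3475 log2 thresholds, the induction metric (share of upregulation mass
per sibling), sibling centroid distances, and the response-TF fold-change
matrix for sensitive bifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import core_expr

__all__ = [
    "LineageTree",
    "TrioConfig",
    "FgfResult",
    "InductionResult",
    "build_lineage",
    "fgf_sensitivity",
    "yates_chi2",
    "categorize",
    "classify_trio_tfs",
    "category_proportions",
    "induction_metric",
    "sibling_distance",
    "fgf_response_matrix",
]

P_FLOOR = 1e-300  # keeps -log10(p) finite


@dataclass
class LineageTree:
    """Directed tree of (stage, state) nodes."""

    stages: list[str]
    parent: dict[str, Optional[str]]
    children: dict[str, list[str]]
    stage_of: dict[str, str]

    @property
    def states(self) -> list[str]:
        return list(self.parent)

    @property
    def roots(self) -> list[str]:
        return [s for s, p in self.parent.items() if p is None]

    @property
    def terminal_stage(self) -> str:
        return self.stages[-1]

    def bifurcations(self) -> list[tuple[str, str, str]]:
        """(parent, child1, child2) for nodes with exactly two children."""
        out = []
        for s in self.states:
            ch = self.children[s]
            if len(ch) == 2:
                out.append((s, ch[0], ch[1]))
        return out

    def quadfurcations(self) -> list[str]:
        """Nodes with more than two children (excluded from trios)."""
        return [s for s in self.states if len(self.children[s]) > 2]

    def quad_pairs(self) -> list[tuple[str, str, str]]:
        """Pairwise inferred bifurcations within each quadfurcation; these
        are kept for motif analysis but never enter trio enumeration."""
        out = []
        for s in self.quadfurcations():
            ch = self.children[s]
            for i in range(len(ch)):
                for j in range(i + 1, len(ch)):
                    out.append((s, ch[i], ch[j]))
        return out

    def trios(self) -> list[tuple[str, str, str]]:
        """Bifurcations with an observed parent (quadfurcations excluded)."""
        return self.bifurcations()

    def subtree(self, state: str) -> list[str]:
        out, stack = [], [state]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(self.children[s])
        return out

    def terminal_descendants(self, state: str) -> list[str]:
        term = self.terminal_stage
        return [s for s in self.subtree(state) if self.stage_of[s] == term]


def build_lineage(
    edges: pd.DataFrame,
    stage_order: Optional[Sequence[str]] = None,
    states: Optional[Iterable[str]] = None,
) -> LineageTree:
    """Build a lineage tree from a (parent_state, child_state, stage) edge
    list; ``stage`` is the stage of the child state.

    Validates acyclicity, unique parentage, and stage consistency (each child
    sits one stage after its parent).  ``states`` optionally restricts/checks
    that every tree node has a cluster assignment.
    """
    required = {"parent_state", "child_state", "stage"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    if stage_order is None:
        stage_order = list(dict.fromkeys(edges["stage"]))
    stage_idx = {s: i for i, s in enumerate(stage_order)}

    parent: dict[str, Optional[str]] = {}
    children: dict[str, list[str]] = {}
    stage_of: dict[str, str] = {}
    for _, row in edges.iterrows():
        p, c, st = row["parent_state"], row["child_state"], row["stage"]
        if st not in stage_idx:
            raise ValueError(f"unknown stage {st!r} on edge {p}->{c}")
        if c in parent and parent[c] is not None:
            raise ValueError(f"state {c!r} has multiple parents")
        parent[c] = p
        stage_of[c] = st
        children.setdefault(c, [])
        children.setdefault(p, []).append(c)
        parent.setdefault(p, None)

    # roots get the stage before their children's; if the edge list never
    # names the root stage, synthesize one in front
    if any(
        s not in stage_of and children[s] and stage_idx[stage_of[children[s][0]]] == 0
        for s in parent
    ):
        stage_order = [f"(pre-{stage_order[0]})"] + list(stage_order)
        stage_idx = {s: i for i, s in enumerate(stage_order)}
    for s in list(parent):
        if s not in stage_of:
            ch = children[s]
            if not ch:
                raise ValueError(f"isolated state {s!r}")
            ci = stage_idx[stage_of[ch[0]]]
            stage_of[s] = stage_order[ci - 1]

    for p, chs in children.items():
        for c in chs:
            if stage_idx[stage_of[c]] != stage_idx[stage_of[p]] + 1:
                raise ValueError(
                    f"edge {p}->{c} skips stages "
                    f"({stage_of[p]!r} -> {stage_of[c]!r})"
                )

    # cycle check by walking to root
    for s in parent:
        seen = set()
        cur: Optional[str] = s
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle detected at state {cur!r}")
            seen.add(cur)
            cur = parent[cur]

    if states is not None:
        missing = set(parent) - set(states)
        if missing:
            raise ValueError(f"tree states without cluster assignment: {sorted(missing)}")

    return LineageTree(
        stages=list(stage_order),
        parent=parent,
        children=children,
        stage_of=stage_of,
    )


@dataclass
class TrioConfig:
    up_threshold: float = 0.3475
    down_threshold: float = -0.3475
    sibling_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.up_threshold > 0 and self.down_threshold == -self.up_threshold):
            raise ValueError("up_threshold must equal -down_threshold and be > 0")


@dataclass
class FgfResult:
    bifurcation: tuple[str, str, str]
    table: Optional[np.ndarray]
    chi2: Optional[float]
    p_value: Optional[float]
    score: Optional[float]
    status: str  # sensitive | insensitive | untestable
    eliminated: Optional[str] = None
    reason: Optional[str] = None


@dataclass
class InductionResult:
    sib1: str
    sib2: str
    mass1: float
    mass2: float
    share1: Optional[float]
    predicted: Optional[str]
    tie: bool = False


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table (textbook formula)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b, c, d = t.ravel()
    n = t.sum()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("degenerate table: zero margin")
    stat = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 / denom
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def fgf_sensitivity(
    tree: LineageTree,
    cell_counts: pd.DataFrame,
    alpha: float = 0.05,
) -> list[FgfResult]:
    """Score every bifurcation for treatment sensitivity.

    ``cell_counts`` is a state x {control, treated} table of cell numbers.
    Each sibling's count is the sum over its terminal-stage descendants.
    Bifurcations lying below an eliminated sibling are reported untestable,
    and the exclusion propagates recursively.
    """
    for col in ("control", "treated"):
        if col not in cell_counts.columns:
            raise ValueError(f"cell_counts needs a {col!r} column")
    counts = cell_counts.reindex(tree.states).fillna(0)

    def arm(state: str, treatment: str) -> int:
        desc = tree.terminal_descendants(state)
        return int(counts.loc[desc, treatment].sum())

    stage_idx = {s: i for i, s in enumerate(tree.stages)}
    bifs = sorted(tree.bifurcations(), key=lambda b: stage_idx[tree.stage_of[b[0]]])
    excluded: set[str] = set()
    results = []
    for p, s1, s2 in bifs:
        bif = (p, s1, s2)
        if p in excluded or s1 in excluded or s2 in excluded:
            results.append(
                FgfResult(bif, None, None, None, None, "untestable",
                          reason="ancestor eliminated")
            )
            continue
        table = np.array(
            [[arm(s1, "control"), arm(s1, "treated")],
             [arm(s2, "control"), arm(s2, "treated")]]
        )
        if table[:, 1].sum() == 0 and table[:, 0].sum() == 0:
            results.append(
                FgfResult(bif, table, None, None, None, "untestable",
                          reason="no cells in either treatment")
            )
            continue
        try:
            chi2, p_val = yates_chi2(table)
        except ValueError as exc:
            results.append(
                FgfResult(bif, table, None, None, None, "untestable",
                          reason=str(exc))
            )
            continue
        score = -np.log10(max(p_val, P_FLOOR)) + 0.0  # avoid -0.0
        if p_val < alpha:
            # eliminated sibling: larger proportional loss under treatment
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(
                    table[:, 0] > 0, table[:, 1] / table[:, 0], np.inf
                )
            elim = (s1, s2)[int(np.argmin(ratios))]
            excluded.update(tree.subtree(elim))
            results.append(
                FgfResult(bif, table, chi2, p_val, score, "sensitive",
                          eliminated=elim)
            )
        else:
            results.append(
                FgfResult(bif, table, chi2, p_val, score, "insensitive")
            )
    return results


def categorize(delta1: float, delta2: float, cfg: Optional[TrioConfig] = None) -> int:
    """Classify an oriented (daughter1, daughter2) pair of log2FC-vs-parent
    values into mechanism categories 1-5; 0 means unclassified.

    Daughter 1 is the sibling with the higher sibling-vs-sibling expression.
    Categories: 1 up/unchanged, 2 up/up, 3 up/down, 4 unchanged/down,
    5 down/down.
    """
    cfg = cfg or TrioConfig()
    up1, up2 = delta1 > cfg.up_threshold, delta2 > cfg.up_threshold
    dn1, dn2 = delta1 < cfg.down_threshold, delta2 < cfg.down_threshold
    if up1 and not up2 and not dn2:
        return 1
    if up1 and up2:
        return 2
    if up1 and dn2:
        return 3
    if not up1 and not dn1 and dn2:
        return 4
    if dn1 and dn2:
        return 5
    return 0


def classify_trio_tfs(
    expr: pd.DataFrame,
    labels: pd.Series,
    parent: str,
    sib1: str,
    sib2: str,
    tf_genes: Sequence[str],
    cfg: Optional[TrioConfig] = None,
) -> pd.DataFrame:
    """Classify sibling-DE transcription factors of one trio.

    TFs with Wilcoxon sibling-vs-sibling p < ``cfg.sibling_alpha`` are kept;
    each daughter's log2FC vs the parent state is thresholded at
    +/-``cfg.up_threshold`` and mapped to categories 1-5 (0 = unclassified).
    Returns a frame indexed by TF with columns (daughter1, daughter2,
    delta1, delta2, sib_log2fc, p_value, category).
    """
    cfg = cfg or TrioConfig()
    labels = labels.reindex(expr.columns)
    cells = {s: list(expr.columns[labels == s]) for s in (parent, sib1, sib2)}
    if not cells[parent]:
        raise ValueError(f"no cells for parent state {parent!r}")
    for s in (sib1, sib2):
        if not cells[s]:
            raise ValueError(f"no cells for sibling state {s!r}")
    tf_genes = [g for g in tf_genes if g in expr.index]
    sub = expr.loc[tf_genes]
    de = core_expr.wilcoxon_de(sub, cells[sib1], cells[sib2])
    de = de[de["p_value"] < cfg.sibling_alpha]
    rows = []
    for gene, row in de.iterrows():
        # orient: daughter 1 is the sibling with higher expression
        if row["log2fc"] >= 0:
            d1, d2 = sib1, sib2
        else:
            d1, d2 = sib2, sib1
        g_expr = expr.loc[[gene]]
        delta1 = core_expr.log2_fold_change(g_expr, cells[d1], cells[parent]).iloc[0]
        delta2 = core_expr.log2_fold_change(g_expr, cells[d2], cells[parent]).iloc[0]
        cat = categorize(delta1, delta2, cfg)
        rows.append(
            (gene, d1, d2, delta1, delta2, abs(row["log2fc"]), row["p_value"], cat)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tf", "daughter1", "daughter2", "delta1", "delta2",
            "sib_log2fc", "p_value", "category",
        ],
    ).set_index("tf")


def category_proportions(categories: Iterable[int]) -> dict:
    """Percentages per mechanism category plus up-/down-in-either summaries.

    Percentages are over classified TFs (categories 1-5; unclassified
    excluded from the denominator so they sum to 100).  Categories 1-3 have
    at least one upregulated daughter, 3-5 at least one downregulated one.
    """
    cats = [int(c) for c in categories]
    classified = [c for c in cats if c in (1, 2, 3, 4, 5)]
    n = len(classified)
    if n == 0:
        return {"n_classified": 0, "n_unclassified": len(cats)}
    pct = {c: 100.0 * classified.count(c) / n for c in (1, 2, 3, 4, 5)}
    up = sum(1 for c in classified if c in (1, 2, 3))
    down = sum(1 for c in classified if c in (3, 4, 5))
    return {
        "n_classified": n,
        "n_unclassified": len(cats) - n,
        "pct": pct,
        "pct_up_in_either": 100.0 * up / n,
        "pct_down_in_either": 100.0 * down / n,
    }


def induction_metric(
    de_tfs: pd.DataFrame,
    sib1: str,
    sib2: str,
    mode: str = "mass",
) -> InductionResult:
    """Predict the induced sibling from DE-TF upregulation shares.

    ``de_tfs`` carries a ``log2fc`` column on the sib1-vs-sib2 comparison.
    ``mode='mass'`` sums |log2FC| per sibling; ``mode='count'`` counts TFs.
    An exact tie yields no prediction.
    """
    if de_tfs.empty:
        raise ValueError("no DE TFs: induction metric undefined")
    lfc = de_tfs["log2fc"].to_numpy(dtype=float)
    if mode == "mass":
        m1 = float(np.abs(lfc[lfc > 0]).sum())
        m2 = float(np.abs(lfc[lfc < 0]).sum())
    elif mode == "count":
        m1 = float((lfc > 0).sum())
        m2 = float((lfc < 0).sum())
    else:
        raise ValueError("mode must be 'mass' or 'count'")
    total = m1 + m2
    if total == 0:
        return InductionResult(sib1, sib2, m1, m2, None, None, tie=True)
    share1 = m1 / total
    if m1 == m2:
        return InductionResult(sib1, sib2, m1, m2, share1, None, tie=True)
    return InductionResult(
        sib1, sib2, m1, m2, share1, sib1 if m1 > m2 else sib2
    )


def sibling_distance(
    coords: pd.DataFrame, labels: pd.Series, sib1: str, sib2: str
) -> float:
    """Euclidean distance between state centroids in a shared embedding."""
    labels = labels.reindex(coords.index)
    for s in (sib1, sib2):
        if (labels == s).sum() == 0:
            raise ValueError(f"state {s!r} absent from embedding")
    c1 = coords[labels == sib1].mean(axis=0).to_numpy()
    c2 = coords[labels == sib2].mean(axis=0).to_numpy()
    return float(np.linalg.norm(c1 - c2))


def fgf_response_matrix(
    sensitive_bifs: Sequence[tuple[str, str]],
    expr: pd.DataFrame,
    labels: pd.Series,
    tf_genes: Sequence[str],
    top_n: int = 50,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray]:
    """log2FC matrix (TF x bifurcation) of sensitive state vs its sibling.

    ``sensitive_bifs`` lists (sensitive_state, sibling_state) pairs.  TFs
    significantly DE in at least one pair qualify; the ``top_n`` most
    variable (by fold-change variance across bifurcations) are kept, and
    rows/columns are ordered by average-linkage clustering.  Returns
    (matrix, row linkage).
    """
    if not sensitive_bifs:
        raise ValueError("need at least one sensitive bifurcation")
    labels = labels.reindex(expr.columns)
    tf_genes = [g for g in tf_genes if g in expr.index]
    sub = expr.loc[tf_genes]
    cols, sig_any = {}, pd.Series(False, index=tf_genes)
    for sens, sib in sensitive_bifs:
        a = list(expr.columns[labels == sens])
        b = list(expr.columns[labels == sib])
        de = core_expr.wilcoxon_de(sub, a, b)
        name = f"{sens}|{sib}"
        cols[name] = de["log2fc"]
        sig_any |= de["p_value"] < alpha
    mat = pd.DataFrame(cols)
    mat = mat.loc[sig_any[sig_any].index]
    if mat.empty:
        warnings.warn("no TF significant in any sensitive bifurcation")
        return mat, np.empty((0, 4))
    if len(mat) > top_n:
        order = mat.var(axis=1).sort_values(ascending=False).index[:top_n]
        mat = mat.loc[sorted(order)]
    if len(mat) > 1:
        Z = hierarchy.linkage(pdist(mat.to_numpy()), method="average")
        mat = mat.iloc[hierarchy.leaves_list(Z)]
    else:
        Z = np.empty((0, 4))
    if mat.shape[1] > 1:
        Zc = hierarchy.linkage(pdist(mat.to_numpy().T), method="average")
        mat = mat.iloc[:, hierarchy.leaves_list(Zc)]
    return mat, Z
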