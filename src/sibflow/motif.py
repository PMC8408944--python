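"""PWM scanning and binding-site over-representation statistics.

Log-odds PWMs from JASPAR-style count matrices, an exact null score
distribution by dynamic programming over discretized per-position scores,
double-stranded scanning, best-in-window hit de-duplication, binomial
enrichment z-scores on dual region representations (upstream windows and
overlapping open-chromatin peaks) with z averaging, peak-to-nearest-gene
tallies, and the 4-variable direct-vs-relay signature matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PWM",
    "MotifHit",
    "EnrichmentResult",
    "RegionConfig",
    "read_jaspar",
    "pwm_score_threshold",
    "scan",
    "dedup_hits",
    "opossum_zscore",
    "combined_zscore",
    "extract_regions",
    "bifurcation_tfbs",
    "ets_signature",
    "peak_gene_tally",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BG = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Log-odds position weight matrix (rows A, C, G, T).

    Built from a count matrix with a total pseudocount distributed by the
    background composition; scores are log2(p / background)."""

    name: str
    log_odds: np.ndarray  # 4 x length
    background: np.ndarray

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: Optional[np.ndarray] = None,
        pseudocount: float = 0.8,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A, C, G, T)")
        bg = UNIFORM_BG if background is None else np.asarray(background, float)
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        probs = (counts + pseudocount * bg[:, None]) / (
            counts.sum(axis=0) + pseudocount
        )
        lo = np.log2(probs / bg[:, None])
        if not np.all(np.isfinite(lo)):
            raise ValueError("non-finite log-odds entries")
        return cls(name=name, log_odds=lo, background=bg)

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def relative(self, raw: float) -> float:
        span = self.max_score - self.min_score
        if span == 0:
            return 1.0
        return (raw - self.min_score) / span

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            log_odds=self.log_odds[::-1, ::-1].copy(),
            background=self.background,
        )


@dataclass
class MotifHit:
    seq_id: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    score: float
    rel_score: float
    pwm: str
    length: int

    @property
    def center(self) -> float:
        return self.start + (self.length - 1) / 2.0


@dataclass
class EnrichmentResult:
    pwm: str
    t: int  # target hits
    T: int  # target nucleotides
    b: int  # background hits
    B: int  # background nucleotides
    rate: float
    mu: float
    sigma: float
    z: Optional[float]
    flagged: bool = False


@dataclass
class RegionConfig:
    upstream_length: int = 1500
    scan_pvalue: float = 0.001
    rel_score_threshold: float = 0.85
    dedup_window: int = 3

    def __post_init__(self) -> None:
        if self.upstream_length <= 0:
            raise ValueError("upstream_length must be positive")
        if not 0 < self.scan_pvalue < 1:
            raise ValueError("scan_pvalue must be in (0, 1)")
        if not 0 < self.rel_score_threshold <= 1:
            raise ValueError("rel_score_threshold must be in (0, 1]")


def read_jaspar(
    path,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.8,
) -> dict[str, PWM]:
    """Parse a JASPAR-2020-dialect PFM file into log-odds PWMs."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = {}
    for m in records:
        name = f"{m.matrix_id} {m.name}".strip() if m.matrix_id else m.name
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        out[name] = PWM.from_counts(name, counts, background, pseudocount)
    return out


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (treated as N)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _BASE_IDX.items():
        codes[arr == ord(base)] = i
    return codes


# ---------------------------------------------------------------------------
# exact p-value calibration


def _int_scores(pwm: PWM, granularity: float) -> np.ndarray:
    return np.round(pwm.log_odds / granularity).astype(np.int64)


def pwm_score_threshold(
    pwm: PWM,
    p: float,
    background: Optional[np.ndarray] = None,
    granularity: float = 1e-4,
) -> float:
    """Raw-score threshold whose null tail probability is <= ``p``.

    The null score distribution is computed exactly by dynamic programming
    over the discretized per-position score grid under an i.i.d. background
    model: the returned value is the smallest grid score s with
    P(score >= s) <= p.  Scores above the grid maximum never occur, so if
    even the top score exceeds p the threshold sits one grid step above it
    (admitting nothing).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    bg = pwm.background if background is None else np.asarray(background, float)
    S = _int_scores(pwm, granularity)
    offset = S.min(axis=0).sum()
    span = int(S.max(axis=0).sum() - offset)
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    for pos in range(pwm.length):
        col = S[:, pos] - S[:, pos].min()
        new = np.zeros(span + 1)
        for base in range(4):
            shift = int(col[base])
            if bg[base] > 0:
                new[shift:] += bg[base] * dist[: span + 1 - shift]
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(-tail, -p, side="left")  # first index with tail <= p
    if idx > span:
        return (span + offset + 1) * granularity
    return (idx + offset) * granularity


# ---------------------------------------------------------------------------
# scanning


def _window_scores(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Scores of every window; windows containing N are -inf."""
    L = table.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([table, np.full((1, L), np.nan)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = padded[windows, np.arange(L)].sum(axis=1)
    return np.where(np.isnan(scores), -np.inf, scores)


def scan(
    seqs: Mapping[str, str],
    pwm: PWM,
    mode: str = "relative",
    rel_threshold: float = 0.85,
    pvalue: float = 0.001,
    background: Optional[np.ndarray] = None,
    granularity: float = 1e-4,
) -> list[MotifHit]:
    """Scan both strands of every sequence for PWM matches.

    ``mode='relative'`` keeps windows with relative score >= ``rel_threshold``;
    ``mode='pvalue'`` keeps windows whose discretized score reaches the
    exact-DP threshold for ``pvalue``.  Hits are ordered (sequence, start,
    strand); N-containing windows are skipped, sequences shorter than the
    motif yield no hits.
    """
    if mode == "relative":
        raw_thr = pwm.min_score + rel_threshold * (pwm.max_score - pwm.min_score)
        passes = lambda s: s >= raw_thr - 1e-12
    elif mode == "pvalue":
        thr = pwm_score_threshold(pwm, pvalue, background, granularity)
        thr_int = int(round(thr / granularity))
        passes = lambda s: int(round(s / granularity)) >= thr_int
    else:
        raise ValueError("mode must be 'relative' or 'pvalue'")

    rc_table = pwm.reverse_complement().log_odds
    hits: list[MotifHit] = []
    for sid in sorted(seqs):
        codes = encode(seqs[sid])
        fwd = _window_scores(codes, pwm.log_odds)
        rev = _window_scores(codes, rc_table)
        for start in range(len(fwd)):
            for strand, score in (("+", fwd[start]), ("-", rev[start])):
                if np.isfinite(score) and passes(score):
                    hits.append(
                        MotifHit(
                            seq_id=sid,
                            start=start,
                            strand=strand,
                            score=float(score),
                            rel_score=pwm.relative(float(score)),
                            pwm=pwm.name,
                            length=pwm.length,
                        )
                    )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def dedup_hits(hits: Sequence[MotifHit], window: int = 3) -> list[MotifHit]:
    """Keep only the best-scoring hit among hits whose centers lie within
    ``window`` bp of each other (across matrices and strands).

    Ties go to the lower start, then the forward strand.  Idempotent.
    """
    kept: list[MotifHit] = []
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    for sid in sorted(by_seq):
        cand = sorted(
            by_seq[sid], key=lambda h: (-h.score, h.start, 0 if h.strand == "+" else 1)
        )
        chosen: list[MotifHit] = []
        for h in cand:
            if all(abs(h.center - k.center) > window for k in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return kept


# ---------------------------------------------------------------------------
# enrichment


def _count_hits(
    seqs: Mapping[str, str],
    pwm: PWM,
    cfg: RegionConfig,
    mode: str = "relative",
) -> tuple[int, int]:
    hits = scan(
        seqs,
        pwm,
        mode=mode,
        rel_threshold=cfg.rel_score_threshold,
        pvalue=cfg.scan_pvalue,
    )
    hits = dedup_hits(hits, cfg.dedup_window)
    total_nt = sum(len(s) for s in seqs.values())
    return len(hits), total_nt


def opossum_zscore(
    target: Mapping[str, str],
    control: Mapping[str, str],
    pwm: PWM,
    cfg: Optional[RegionConfig] = None,
    mode: str = "relative",
    continuity: bool = False,
) -> EnrichmentResult:
    """Binomial over-representation z-score of PWM hits per nucleotide.

    The control set fixes the hit rate p = b/B; the target hit count t is
    compared with mu = p*T, sigma = sqrt(T p (1-p)).  sigma == 0 (rate 0 or
    1) yields an undefined, flagged z.
    """
    if not target or not control:
        raise ValueError("target and control sets must be nonempty")
    cfg = cfg or RegionConfig()
    t, T = _count_hits(target, pwm, cfg, mode)
    b, B = _count_hits(control, pwm, cfg, mode)
    rate = b / B
    mu = rate * T
    sigma = math.sqrt(T * rate * (1.0 - rate))
    if sigma == 0:
        return EnrichmentResult(pwm.name, t, T, b, B, rate, mu, sigma, None, True)
    num = t - mu
    if continuity:
        num -= 0.5 * np.sign(num)
    return EnrichmentResult(pwm.name, t, T, b, B, rate, mu, sigma, num / sigma)


def combined_zscore(
    z_upstream: Optional[float], z_atac: Optional[float]
) -> tuple[Optional[float], bool]:
    """Mean of the finite z-scores; flags single-source results."""
    vals = [z for z in (z_upstream, z_atac) if z is not None and np.isfinite(z)]
    if not vals:
        return None, True
    return float(np.mean(vals)), len(vals) < 2


# ---------------------------------------------------------------------------
# regions


def extract_regions(
    gene_models: pd.DataFrame,
    genome: Mapping[str, str],
    peaks: Optional[pd.DataFrame],
    cfg: Optional[RegionConfig] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> tuple[dict[str, str], dict[str, str], list[str]]:
    """Strand-aware upstream windows and the whole ATAC peaks they overlap.

    ``gene_models`` has columns (gene, contig, start, end, strand) with
    0-based half-open coordinates.  Upstream windows are clamped at contig
    edges.  Returns (upstream sequences keyed by gene, peak sequences keyed
    by ``gene|peak``, skipped gene ids).
    """
    cfg = cfg or RegionConfig()
    models = gene_models.set_index("gene")
    if gene_ids is None:
        gene_ids = list(models.index)
    skipped: list[str] = []
    upstream: dict[str, str] = {}
    atac: dict[str, str] = {}
    for gene in gene_ids:
        if gene not in models.index:
            skipped.append(gene)
            continue
        row = models.loc[gene]
        contig = row["contig"]
        if contig not in genome:
            skipped.append(gene)
            continue
        clen = len(genome[contig])
        if row["strand"] == "+":
            lo, hi = int(row["start"]) - cfg.upstream_length, int(row["start"])
        else:
            lo, hi = int(row["end"]), int(row["end"]) + cfg.upstream_length
        lo_c, hi_c = max(lo, 0), min(hi, clen)
        if hi_c - lo_c < hi - lo:
            warnings.warn(
                f"upstream window for {gene} clamped to [{lo_c}, {hi_c})"
            )
        if hi_c <= lo_c:
            skipped.append(gene)
            continue
        seq = genome[contig][lo_c:hi_c]
        if row["strand"] == "-":
            seq = revcomp(seq)
        upstream[gene] = seq
        if peaks is not None:
            for _, pk in peaks[peaks["contig"] == contig].iterrows():
                ps, pe = int(pk["start"]), int(pk["end"])
                if ps < hi_c and pe > lo_c:  # any overlap keeps the whole peak
                    atac[f"{gene}|{contig}:{ps}-{pe}"] = genome[contig][ps:pe]
    return upstream, atac, skipped


def _set_zscore(
    target: Mapping[str, str],
    control: Mapping[str, str],
    pwm: PWM,
    cfg: RegionConfig,
) -> Optional[float]:
    if not target or not control:
        return None
    res = opossum_zscore(target, control, pwm, cfg)
    return res.z


def bifurcation_tfbs(
    up_sib1: Mapping[str, Mapping[str, str]],
    up_sib2: Mapping[str, Mapping[str, str]],
    enriched_sib1: Mapping[str, Mapping[str, str]],
    depleted_sib1: Mapping[str, Mapping[str, str]],
    enriched_sib2: Mapping[str, Mapping[str, str]],
    depleted_sib2: Mapping[str, Mapping[str, str]],
    pwm: PWM,
    cfg: Optional[RegionConfig] = None,
) -> dict[str, Optional[float]]:
    """The three combined z-scores of one bifurcation.

    Each argument maps representation name ('upstream', 'atac') to a
    sequence set.  ``by_sibs`` contrasts genes up in sibling 1 vs genes up
    in sibling 2; ``by_enriched_sibN`` contrasts genes up vs down in sibling
    N's own all-other-states comparison.
    """
    cfg = cfg or RegionConfig()

    def combined(tgt, ctl) -> Optional[float]:
        zs = [
            _set_zscore(tgt.get(rep, {}), ctl.get(rep, {}), pwm, cfg)
            for rep in ("upstream", "atac")
        ]
        z, _ = combined_zscore(*zs)
        return z

    return {
        "by_sibs": combined(up_sib1, up_sib2),
        "by_enriched_sib1": combined(enriched_sib1, depleted_sib1),
        "by_enriched_sib2": combined(enriched_sib2, depleted_sib2),
    }


def ets_signature(
    variables: pd.DataFrame,
    fgf_score: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Order the 4-variable (by-sibs z, per-sibling enriched z's, proxy-TF
    log2FC) signature matrix by average-linkage clustering.

    Rows with missing entries are retained in the output but excluded from
    clustering (appended after the ordered block and listed).  The optional
    dependency score column is appended for display only.
    """
    if variables.shape[1] != 4:
        raise ValueError("signature matrix must have exactly 4 columns")
    complete = variables.dropna()
    missing = [i for i in variables.index if i not in complete.index]
    if len(complete) > 1:
        Z = hierarchy.linkage(pdist(complete.to_numpy()), method="average")
        ordered = complete.iloc[hierarchy.leaves_list(Z)]
    else:
        Z = np.empty((0, 4))
        ordered = complete
    out = pd.concat([ordered, variables.loc[missing]])
    if fgf_score is not None:
        out = out.assign(fgf_score=fgf_score.reindex(out.index))
    return out, Z, missing


def peak_gene_tally(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    hits: Sequence[MotifHit],
    dedup_window: int = 3,
) -> pd.DataFrame:
    """Assign each peak to its nearest gene model and tally per-gene open
    chromatin length and deduplicated motif-hit counts.

    ``hits`` carry seq_ids of the form ``contig:start-end`` (one per peak).
    Equidistant genes tie-break to the lexicographically smaller gene id.
    """
    deduped = dedup_hits(list(hits), dedup_window)
    hit_counts: dict[str, int] = {}
    for h in deduped:
        hit_counts[h.seq_id] = hit_counts.get(h.seq_id, 0) + 1

    models = gene_models.sort_values("gene")
    rows = []
    for _, pk in peaks.iterrows():
        contig, ps, pe = pk["contig"], int(pk["start"]), int(pk["end"])
        cand = models[models["contig"] == contig]
        if cand.empty:
            continue
        gs = cand["start"].to_numpy()
        ge = cand["end"].to_numpy()
        dist = np.where(
            (ps < ge) & (pe > gs), 0, np.where(gs >= pe, gs - pe, ps - ge)
        )
        best = int(np.argmin(dist))  # argmin takes first -> lexicographic tie-break
        rows.append(
            (
                cand["gene"].iloc[best],
                pe - ps,
                hit_counts.get(f"{contig}:{ps}-{pe}", 0),
            )
        )
    df = pd.DataFrame(rows, columns=["gene", "peak_length", "n_sites"])
    return df.groupby("gene").sum()
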