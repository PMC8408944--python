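"""Synthetic data with machine-readable planted truth.

Generates lineage-structured negative-binomial UMI counts with per-mother
batch offsets and treatment-dependent state ablation, per-mother SNP
genotypes with per-cell dropout and error, and promoter sequences with
planted consensus-motif densities.  Every generator is deterministic given
its seed, and the emitted truth indexes only objects that exist in the
corresponding matrices and sequences.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import core_expr
from .motif import PWM

__all__ = [
    "PlantedTF",
    "SimSpec",
    "SimTruth",
    "default_spec",
    "default_pwms",
    "simulate_counts",
    "simulate_genotypes",
    "simulate_promoters",
    "write_fixture_bundle",
]

# per-category multiplicative effects in log2 units on (daughter1, daughter2)
# vs the parent mean, for an effect size e; daughter1 is the high sibling
_CATEGORY_DELTAS = {
    1: lambda e: (e, 0.0),
    2: lambda e: (e, e / 2.0),
    3: lambda e: (e, -e),
    4: lambda e: (0.0, -e),
    5: lambda e: (-e / 2.0, -e),
}


@dataclass
class PlantedTF:
    """One planted differential TF: which bifurcation, which mechanism
    category (1-5), the effect size in log2 units, and whether daughter 1
    (the high sibling) is the bifurcation's induced state."""

    bifurcation: str  # parent state
    gene: str
    category: int
    effect: float
    daughter1: str  # child state carrying the higher expression

    def deltas(self) -> tuple[float, float]:
        if self.category not in _CATEGORY_DELTAS:
            raise ValueError(
                f"planted TF {self.gene!r}: invalid category {self.category}"
            )
        if self.effect <= 0:
            raise ValueError(
                f"planted TF {self.gene!r}: effect must be positive for "
                f"category {self.category}"
            )
        return _CATEGORY_DELTAS[self.category](self.effect)


@dataclass
class SimSpec:
    n_mothers: int = 3
    cells_per_state: int = 60
    n_genes: int = 300
    n_tfs: int = 60
    stages: tuple[str, ...] = ("stage1", "stage2", "stage3")
    edges: tuple[tuple[str, str, str], ...] = ()  # (parent, child, child stage)
    nb_dispersion: float = 10.0
    maternal_offset_sd: float = 0.0
    depth_sd: float = 0.3
    base_mean_log_sd: float = 0.5
    tf_base_mean: float = 8.0
    marker_genes_per_state: int = 0  # 0 = no marker programs
    marker_effect: float = 2.0  # log2 units; gives every state an identity
    planted_de: tuple[PlantedTF, ...] = ()
    ablated_states: tuple[tuple[str, str], ...] = ()  # (state, treatment)
    induced_sibling: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def tf_genes(self) -> list[str]:
        return [f"tf{i:03d}" for i in range(self.n_tfs)]

    def all_genes(self) -> list[str]:
        tfs = self.tf_genes()
        others = [f"g{i:03d}" for i in range(self.n_genes - self.n_tfs)]
        return tfs + others

    def state_markers(self) -> dict[str, list[str]]:
        """Deterministic state -> marker-gene assignment, drawn from the end
        of the non-TF gene list so the leading genes stay program-free."""
        k = self.marker_genes_per_state
        if k == 0:
            return {}
        non_tf = [g for g in self.all_genes() if g not in set(self.tf_genes())]
        states = self.lineage_states()
        if k * len(states) > len(non_tf):
            raise ValueError("not enough non-TF genes for state markers")
        out = {}
        for i, s in enumerate(states):
            block = non_tf[len(non_tf) - (i + 1) * k : len(non_tf) - i * k]
            out[s] = block
        return out

    def lineage_states(self) -> list[str]:
        states = []
        for p, c, _ in self.edges:
            for s in (p, c):
                if s not in states:
                    states.append(s)
        return states

    def children(self, state: str) -> list[str]:
        return [c for p, c, _ in self.edges if p == state]

    def parent_of(self, state: str) -> Optional[str]:
        for p, c, _ in self.edges:
            if c == state:
                return p
        return None

    def validate(self) -> None:
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        states = set(self.lineage_states())
        tf_set = set(self.tf_genes())
        for pl in self.planted_de:
            pl.deltas()  # raises on invalid category/effect
            if pl.gene not in tf_set:
                raise ValueError(f"planted TF {pl.gene!r} not in the TF list")
            kids = self.children(pl.bifurcation)
            if len(kids) != 2:
                raise ValueError(
                    f"planted TF {pl.gene!r}: {pl.bifurcation!r} is not a bifurcation"
                )
            if pl.daughter1 not in kids:
                raise ValueError(
                    f"planted TF {pl.gene!r}: daughter1 {pl.daughter1!r} is not a "
                    f"child of {pl.bifurcation!r}"
                )
        for state, treatment in self.ablated_states:
            if state not in states:
                raise ValueError(f"ablated state {state!r} is not a lineage node")
            if treatment not in ("control", "treated"):
                raise ValueError(f"unknown treatment {treatment!r}")


@dataclass
class SimTruth:
    mother_of: dict[str, str] = field(default_factory=dict)
    state_of: dict[str, str] = field(default_factory=dict)
    induced_sibling: dict[str, str] = field(default_factory=dict)
    tf_category: dict[str, dict] = field(default_factory=dict)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    mother_genotypes: Optional[list[list[int]]] = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _default_edges() -> tuple[tuple[str, str, str], ...]:
    edges = []
    for root in ("A", "B"):
        for i in (1, 2):
            edges.append((root, f"{root}{i}", "stage2"))
            for leaf in ("a", "b"):
                edges.append((f"{root}{i}", f"{root}{i}{leaf}", "stage3"))
    return tuple(edges)


def default_spec(
    seed: int = 0,
    cells_per_state: int = 60,
    maternal_offset_sd: float = 0.0,
    n_mothers: int = 3,
) -> SimSpec:
    """The standard fixture: a two-root, three-stage tree with six
    bifurcations, planted TFs in every mechanism category (70% of planted
    upregulation mass on the induced sibling), and the treated condition
    ablating the A2 subtree."""
    edges = _default_edges()
    bifs = ["A", "B", "A1", "A2", "B1", "B2"]
    planted: list[PlantedTF] = []
    induced: dict[str, str] = {}
    gi = 0
    for bif in bifs:
        kids = sorted({c for p, c, _ in edges if p == bif})
        induced[bif] = kids[0]
        # categories on the induced daughter: most mass up in daughter1
        for cat, eff in ((1, 1.2), (1, 1.4), (2, 1.2), (3, 1.2), (4, 1.2), (5, 1.2)):
            planted.append(
                PlantedTF(bif, f"tf{gi:03d}", cat, eff, daughter1=kids[0])
            )
            gi += 1
        # a smaller share oriented to the other daughter
        for cat, eff in ((1, 0.8), (4, 0.8)):
            planted.append(
                PlantedTF(bif, f"tf{gi:03d}", cat, eff, daughter1=kids[1])
            )
            gi += 1
    ablate = [("A2", "treated"), ("A2a", "treated"), ("A2b", "treated")]
    return SimSpec(
        n_mothers=n_mothers,
        cells_per_state=cells_per_state,
        n_genes=300,
        n_tfs=gi + 10,
        edges=edges,
        marker_genes_per_state=4,
        maternal_offset_sd=maternal_offset_sd,
        planted_de=tuple(planted),
        ablated_states=tuple(ablate),
        induced_sibling=induced,
        seed=seed,
    )


def _state_means(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    genes = spec.all_genes()
    tf_set = set(spec.tf_genes())
    base = rng.lognormal(mean=1.0, sigma=spec.base_mean_log_sd, size=len(genes))
    base = pd.Series(base, index=genes)
    planted_genes = {pl.gene for pl in spec.planted_de}
    # planted TFs get a stable, comfortably detectable baseline
    for g in planted_genes:
        base[g] = spec.tf_base_mean
    states = spec.lineage_states()
    means = pd.DataFrame(
        np.tile(base.to_numpy()[:, None], (1, len(states))),
        index=genes,
        columns=states,
    )
    # propagate multiplicative planted effects down the tree (children first
    # inherit the parent's vector, then bifurcation effects are applied)
    order = [s for s in states if spec.parent_of(s) is None]
    frontier = list(order)
    while frontier:
        nxt = []
        for p in frontier:
            for c in spec.children(p):
                means[c] = means[p]
                nxt.append(c)
        for pl in spec.planted_de:
            kids = spec.children(pl.bifurcation)
            if kids and kids[0] in nxt:
                d1, d2 = pl.deltas()
                other = [k for k in kids if k != pl.daughter1][0]
                means.loc[pl.gene, pl.daughter1] = (
                    means.loc[pl.gene, pl.bifurcation] * 2.0**d1
                )
                means.loc[pl.gene, other] = (
                    means.loc[pl.gene, pl.bifurcation] * 2.0**d2
                )
        frontier = nxt
    # state-specific marker programs (not inherited) so each state has a
    # recoverable identity in expression space
    for state, markers in spec.state_markers().items():
        means.loc[markers, state] *= 2.0**spec.marker_effect
    return means


def simulate_counts(spec: SimSpec) -> tuple[core_expr.CountMatrix, SimTruth]:
    """Negative-binomial counts: mean = state mean x mother offset x depth.

    Variance is mu + mu^2/theta (gamma-Poisson mixture); theta -> inf gives
    the Poisson limit.  The treated condition omits cells of ablated states.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = _state_means(spec, rng)
    genes = spec.all_genes()
    states = spec.lineage_states()
    ablated = set(spec.ablated_states)

    offsets = {}
    for m in range(spec.n_mothers):
        if spec.maternal_offset_sd > 0:
            offsets[m] = np.exp(
                rng.normal(0.0, spec.maternal_offset_sd, size=len(genes))
            )
        else:
            offsets[m] = np.ones(len(genes))

    barcodes, cell_meta, blocks = [], [], []
    for state in states:
        stage = _stage_of(spec, state)
        for treatment in ("control", "treated"):
            if (state, treatment) in ablated:
                continue
            for i in range(spec.cells_per_state):
                mother = i % spec.n_mothers
                depth = (
                    np.exp(rng.normal(0.0, spec.depth_sd))
                    if spec.depth_sd > 0
                    else 1.0
                )
                mu = means[state].to_numpy() * offsets[mother] * depth
                if np.isfinite(spec.nb_dispersion):
                    lam = rng.gamma(
                        spec.nb_dispersion, mu / spec.nb_dispersion
                    )
                else:
                    lam = mu
                blocks.append(rng.poisson(lam))
                bc = f"{state}.{treatment}.{i:04d}"
                barcodes.append(bc)
                cell_meta.append((bc, stage, treatment, f"mother{mother + 1}", state))

    counts = pd.DataFrame(
        np.column_stack(blocks), index=genes, columns=barcodes, dtype=int
    )
    cells = pd.DataFrame(
        cell_meta, columns=["cell", "stage", "treatment", "mother", "state"]
    ).set_index("cell")
    gene_meta = pd.DataFrame(
        {"is_tf": [g in set(spec.tf_genes()) for g in genes]}, index=genes
    )
    cm = core_expr.CountMatrix(counts=counts, cells=cells, genes=gene_meta)
    truth = SimTruth(
        mother_of=dict(cells["mother"]),
        state_of=dict(cells["state"]),
        induced_sibling=dict(spec.induced_sibling),
        tf_category={
            pl.gene: {
                "bifurcation": pl.bifurcation,
                "category": pl.category,
                "effect": pl.effect,
                "daughter1": pl.daughter1,
            }
            for pl in spec.planted_de
        },
    )
    return cm, truth


def _stage_of(spec: SimSpec, state: str) -> str:
    for p, c, st in spec.edges:
        if c == state:
            return st
    return spec.stages[0]  # roots


def simulate_genotypes(
    n_mothers: int,
    n_snps: int,
    dropout_rate: float,
    error_rate: float,
    cells_per_mother: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-cell dosages inherited from Beta-allele-frequency mother genotypes.

    Entries go missing (NaN) independently at ``dropout_rate`` and are
    resampled to a different dosage at ``error_rate``.
    """
    if n_mothers < 2:
        raise ValueError("demultiplexing is undefined for fewer than 2 mothers")
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    for name, rate in (("dropout_rate", dropout_rate), ("error_rate", error_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = rng.beta(2.0, 2.0, size=n_snps)
    mothers = rng.binomial(2, freqs, size=(n_mothers, n_snps)).astype(float)

    cells, rows, mother_of = [], [], {}
    for m in range(n_mothers):
        for i in range(cells_per_mother):
            g = mothers[m].copy()
            if error_rate > 0:
                flip = rng.random(n_snps) < error_rate
                for j in np.where(flip)[0]:
                    alts = [d for d in (0.0, 1.0, 2.0) if d != g[j]]
                    g[j] = alts[rng.integers(len(alts))]
            if dropout_rate > 0:
                g[rng.random(n_snps) < dropout_rate] = np.nan
            bc = f"m{m + 1}.c{i:04d}"
            cells.append(bc)
            rows.append(g)
            mother_of[bc] = f"mother{m + 1}"
    dosages = pd.DataFrame(
        np.vstack(rows),
        index=cells,
        columns=[f"snp{j:05d}" for j in range(n_snps)],
    )
    truth = SimTruth(
        mother_of=mother_of, mother_genotypes=mothers.astype(int).tolist()
    )
    return dosages, truth


def simulate_promoters(
    gene_sets: Mapping[str, Sequence[str]],
    pwm: PWM,
    planted_density_per_set: Mapping[str, float],
    seq_length: int = 1500,
    background_freqs: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """I.i.d. background sequences with non-overlapping consensus insertions.

    Each sequence in set s receives Poisson(density_s * length / 1000)
    insertions of the PWM consensus at uniformly drawn, non-overlapping
    positions; positions are recorded in the truth.
    """
    bg = np.asarray(
        background_freqs if background_freqs is not None else [0.25] * 4, float
    )
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    for s, d in planted_density_per_set.items():
        if d < 0:
            raise ValueError(f"density for set {s!r} must be >= 0")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus
    L = len(consensus)
    seqs: dict[str, str] = {}
    truth_pos: dict[str, list[int]] = {}
    for set_name, ids in gene_sets.items():
        density = planted_density_per_set.get(set_name, 0.0)
        lam = density * seq_length / 1000.0
        if lam * L > seq_length:
            raise ValueError(
                f"set {set_name!r}: expected insertions ({lam:.1f} x {L} bp) "
                f"exceed sequence capacity ({seq_length} bp)"
            )
        for sid in ids:
            base = rng.choice(4, size=seq_length, p=bg)
            seq = list("ACGT"[i] for i in base)
            n_sites = rng.poisson(lam)
            placed: list[int] = []
            attempts = 0
            while len(placed) < n_sites:
                attempts += 1
                if attempts > 200 * max(n_sites, 1):
                    raise ValueError(
                        f"could not place {n_sites} non-overlapping sites in "
                        f"{sid!r} ({seq_length} bp)"
                    )
                pos = int(rng.integers(0, seq_length - L + 1))
                if all(abs(pos - q) >= L for q in placed):
                    placed.append(pos)
            for pos in placed:
                seq[pos : pos + L] = consensus
            seqs[sid] = "".join(seq)
            if placed:
                truth_pos[sid] = sorted(placed)
    return seqs, SimTruth(motif_positions=truth_pos)


def default_pwms() -> dict[str, np.ndarray]:
    """Two toy count matrices: an Ets-like GGAA-core motif (planted) and an
    unrelated control motif."""
    ets = np.array(
        [
            # A C G T per column, consensus ACAGGAAGT-ish core CAGGAAGT
            [20, 0, 80, 0, 0, 0, 95, 90, 5],
            [10, 85, 5, 0, 0, 0, 0, 5, 10],
            [60, 5, 10, 100, 100, 100, 0, 0, 75],
            [10, 10, 5, 0, 0, 0, 5, 5, 10],
        ],
        dtype=float,
    )
    ctrl = np.array(
        [
            [0, 90, 0, 5, 0, 85, 0, 10],
            [90, 0, 5, 0, 95, 0, 10, 0],
            [5, 5, 5, 95, 0, 10, 0, 85],
            [5, 5, 90, 0, 5, 5, 90, 5],
        ],
        dtype=float,
    )
    return {"ETSLIKE": ets, "CTRLMOTIF": ctrl}


def write_fixture_bundle(outdir: str, spec: SimSpec) -> dict[str, str]:
    """Emit a complete plain-text fixture consumable by the CLI pipeline.

    Writes MTX counts + barcodes/genes TSVs, cell metadata, a dosage TSV, a
    per-gene synthetic genome FASTA with promoters, GFF3 gene models, BED
    peaks, a JASPAR PFM file, the lineage edge list, a TF list, and the
    truth JSON.  Returns the path of every file written.
    """
    from . import io as sio

    os.makedirs(outdir, exist_ok=True)
    spec.validate()
    cm, truth = simulate_counts(spec)
    per_mother = int(pd.Series(truth.mother_of).value_counts().max())
    dosages, gtruth = simulate_genotypes(
        n_mothers=spec.n_mothers,
        n_snps=1000,
        dropout_rate=0.5,
        error_rate=0.01,
        cells_per_mother=per_mother,
        seed=spec.seed + 1,
    )
    # re-key genotype cells to the count-matrix barcodes (cells inherit the
    # mother recorded in the count truth, in order)
    by_mother: dict[str, list[str]] = {}
    for bc, m in gtruth.mother_of.items():
        by_mother.setdefault(m, []).append(bc)
    newindex, used = [], {m: 0 for m in by_mother}
    for bc in cm.counts.columns:
        m = truth.mother_of[bc]
        src = by_mother[m][used[m]]
        used[m] += 1
        newindex.append(src)
    dosages = dosages.loc[newindex]
    dosages.index = cm.counts.columns

    # promoters: planted motif in the genes upregulated in induced siblings
    counts_mats = default_pwms()
    pwm = PWM.from_counts("ETSLIKE", counts_mats["ETSLIKE"])
    planted_up = sorted(
        {
            pl.gene
            for pl in spec.planted_de
            if pl.daughter1 == spec.induced_sibling.get(pl.bifurcation)
            and pl.category in (1, 2, 3)
        }
    )
    other_genes = [g for g in spec.all_genes() if g not in set(planted_up)]
    seqs, ptruth = simulate_promoters(
        {"planted": planted_up, "background": other_genes},
        pwm,
        {"planted": 5.0, "background": 0.5},
        seq_length=1500,
        seed=spec.seed + 2,
    )
    truth.motif_positions = ptruth.motif_positions
    truth.mother_genotypes = gtruth.mother_genotypes

    gene_len = 200
    genome = {}
    models, peaks = [], []
    for g in spec.all_genes():
        contig = f"chr_{g}"
        rng = np.random.default_rng(
            zlib.crc32(f"{spec.seed}:{g}".encode()) & 0x7FFFFFFF
        )
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=gene_len))
        genome[contig] = seqs[g] + body
        models.append((g, contig, 1500, 1500 + gene_len, "+"))
        peaks.append((contig, 400, 900, f"peak_{g}"))
    models_df = pd.DataFrame(
        models, columns=["gene", "contig", "start", "end", "strand"]
    )
    peaks_df = pd.DataFrame(peaks, columns=["contig", "start", "end", "name"])

    paths = {}
    paths["counts"] = sio.write_mtx(outdir, cm)
    paths["cells"] = os.path.join(outdir, "cells.tsv")
    cm.cells.to_csv(paths["cells"], sep="\t")
    paths["dosages"] = os.path.join(outdir, "dosages.tsv")
    sio.write_dosages(paths["dosages"], dosages)
    paths["lineage"] = os.path.join(outdir, "lineage.tsv")
    sio.write_lineage(paths["lineage"], spec.edges)
    paths["genome"] = os.path.join(outdir, "genome.fa")
    sio.write_fasta(paths["genome"], genome)
    paths["gff"] = os.path.join(outdir, "models.gff3")
    sio.write_gff3(paths["gff"], models_df)
    paths["peaks"] = os.path.join(outdir, "peaks.bed")
    sio.write_bed(paths["peaks"], peaks_df)
    paths["pwms"] = os.path.join(outdir, "motifs.jaspar")
    sio.write_jaspar(paths["pwms"], counts_mats)
    paths["tfs"] = os.path.join(outdir, "tf_list.tsv")
    pd.Series(spec.tf_genes(), name="gene").to_csv(
        paths["tfs"], sep="\t", index=False
    )
    paths["truth"] = os.path.join(outdir, "truth.json")
    truth.to_json(paths["truth"])
    return paths
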