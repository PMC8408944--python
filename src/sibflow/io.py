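"""Readers and writers for the plain-text interchange formats.

Matrix Market counts with barcode/gene TSVs, dense count TSVs, dosage
matrices (cells x SNPs, NA for missing), lineage edge lists, FASTA, BED
(0-based half-open), GFF3 (1-based, converted on read), JASPAR PFMs, and
VCF genotype dosages.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core_expr import CountMatrix

__all__ = [
    "read_mtx",
    "write_mtx",
    "read_counts_tsv",
    "read_dosages",
    "write_dosages",
    "read_vcf_dosages",
    "read_lineage",
    "write_lineage",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "write_jaspar",
]


def write_mtx(outdir: str, cm: CountMatrix, prefix: str = "") -> str:
    os.makedirs(outdir, exist_ok=True)
    mtx_path = os.path.join(outdir, f"{prefix}matrix.mtx")
    spio.mmwrite(mtx_path, sparse.csr_matrix(cm.counts.to_numpy()))
    pd.Series(cm.counts.columns).to_csv(
        os.path.join(outdir, f"{prefix}barcodes.tsv"),
        sep="\t", index=False, header=False,
    )
    cm.genes.to_csv(os.path.join(outdir, f"{prefix}genes.tsv"), sep="\t")
    return mtx_path


def read_mtx(
    indir: str, cells_tsv: Optional[str] = None, prefix: str = ""
) -> CountMatrix:
    mat = spio.mmread(os.path.join(indir, f"{prefix}matrix.mtx")).toarray()
    barcodes = pd.read_csv(
        os.path.join(indir, f"{prefix}barcodes.tsv"), sep="\t", header=None
    )[0].tolist()
    genes = pd.read_csv(
        os.path.join(indir, f"{prefix}genes.tsv"), sep="\t", index_col=0
    )
    if cells_tsv is None:
        cells_tsv = os.path.join(indir, f"{prefix}cells.tsv")
    if os.path.exists(cells_tsv):
        cells = pd.read_csv(cells_tsv, sep="\t", index_col=0)
        cells = cells.loc[barcodes]
    else:
        cells = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    counts = pd.DataFrame(
        mat.astype(int), index=genes.index, columns=barcodes
    )
    return CountMatrix(counts=counts, cells=cells, genes=genes)


def read_counts_tsv(path: str, cells_tsv: Optional[str] = None) -> CountMatrix:
    """Dense genes-x-cells TSV with a gene-id index column."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if cells_tsv is not None:
        cells = pd.read_csv(cells_tsv, sep="\t", index_col=0).loc[counts.columns]
    else:
        cells = pd.DataFrame(index=counts.columns)
    genes = pd.DataFrame(index=counts.index)
    return CountMatrix(counts=counts.astype(int), cells=cells, genes=genes)


def write_dosages(path: str, dosages: pd.DataFrame) -> None:
    dosages.to_csv(path, sep="\t", na_rep="NA")


def read_dosages(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def read_vcf_dosages(path: str) -> pd.DataFrame:
    """Per-sample alternate-allele dosages from an (uncompressed) VCF.

    Unphased/phased diploid GTs map to 0/1/2; missing calls to NaN.
    """
    samples: list[str] = []
    snp_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid = fields[0], fields[1], fields[2]
            snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
            gt_idx = fields[8].split(":").index("GT")
            row = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) > 0 for a in alleles)))
            rows.append(row)
    if not samples:
        raise ValueError(f"no sample columns in VCF {path!r}")
    return pd.DataFrame(np.array(rows).T, index=samples, columns=snp_ids)


def write_lineage(path: str, edges: Sequence[tuple[str, str, str]]) -> None:
    pd.DataFrame(
        list(edges), columns=["parent_state", "child_state", "stage"]
    ).to_csv(path, sep="\t", index=False)


def read_lineage(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(path: str, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_bed(path: str, peaks: pd.DataFrame) -> None:
    cols = ["contig", "start", "end"] + (
        ["name"] if "name" in peaks.columns else []
    )
    peaks[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["contig", "start", "end", "name"][: df.shape[1]]
    return df


def write_gff3(path: str, models: pd.DataFrame) -> None:
    """Write gene features; input coordinates are 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in models.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(row["contig"]), "sibflow", "gene",
                        str(int(row["start"]) + 1), str(int(row["end"])),
                        ".", row["strand"], ".", f"ID={row['gene']}",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str) -> pd.DataFrame:
    """Gene features as (gene, contig, start, end, strand), 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene = attrs.get("ID") or attrs.get("gene_id") or f"{f[0]}:{f[3]}"
            rows.append((gene, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return pd.DataFrame(
        rows, columns=["gene", "contig", "start", "end", "strand"]
    )


def write_jaspar(path: str, matrices: Mapping[str, np.ndarray]) -> None:
    """JASPAR 2020 PFM dialect: '>ID NAME' then 'A [ ... ]' rows."""
    with open(path, "w") as fh:
        for name, counts in matrices.items():
            fh.write(f">{name} {name}\n")
            for base, row in zip("ACGT", np.asarray(counts)):
                vals = " ".join(f"{v:6.0f}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")
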