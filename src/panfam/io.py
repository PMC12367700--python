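"""Readers and writers for the bundle's on-disk formats.

FASTA goes through Biopython SeqIO. GFF3 is 1-based inclusive on disk and
converted to 0-based half-open :class:`~panfam.variation.GeneLocus` on
read. TE tables are 0-based half-open TSV (chrom, start, end, strand,
code); PAV tables are TSV (accession, chrom, start, end, state).
Expression matrices are TSV with a gene_id index column. PWMs are
MEME-minimal motif files (parsed with Bio.motifs) or plain 4 x w count
tables.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import ProteinRecord
from .network import Pwm
from .variation import GeneLocus, PavEvent, TEFeature

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_protein_records",
    "read_gff3",
    "write_gff3",
    "read_te_table",
    "write_te_table",
    "read_pav_table",
    "write_pav_table",
    "read_expression",
    "write_expression",
    "read_pwm",
    "write_pwm_meme",
    "read_go_map",
    "write_go_map",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_records(path: str | Path, accession_id: str) -> list[ProteinRecord]:
    """Per-accession protein FASTA -> ProteinRecords.

    Record ids may be plain gene ids or 'accession|gene_id'; the accession
    component, when present, must agree with ``accession_id``.
    """
    out = []
    for rid, seq in read_fasta(path).items():
        if "|" in rid:
            acc, gene = rid.split("|", 1)
            if acc != accession_id:
                raise ValueError(f"record {rid} does not belong to {accession_id}")
        else:
            gene = rid
        out.append(ProteinRecord(gene_id=gene, accession_id=accession_id, sequence=seq))
    return out


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneLocus]:
    """Parse gene features from GFF3 into 0-based half-open loci."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"{fields[0]}:{fields[3]}")
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,  # 1-based inclusive -> half-open
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return loci


def write_gff3(path: str | Path, loci: Sequence[GeneLocus], source: str = "panfam") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


_TE_COLUMNS = ["chrom", "start", "end", "strand", "code"]


def read_te_table(path: str | Path) -> list[TEFeature]:
    df = pd.read_csv(path, sep="\t")
    return [
        TEFeature(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            strand=str(r.strand), code=str(r.code),
        )
        for r in df.itertuples()
    ]


def write_te_table(path: str | Path, tes: Sequence[TEFeature]) -> None:
    pd.DataFrame(
        [{c: getattr(t, c) for c in _TE_COLUMNS} for t in tes], columns=_TE_COLUMNS
    ).to_csv(path, sep="\t", index=False)


_PAV_COLUMNS = ["accession_id", "chrom", "start", "end", "state"]


def read_pav_table(path: str | Path) -> list[PavEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        PavEvent(
            accession_id=str(r.accession_id), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), state=str(r.state),
        )
        for r in df.itertuples()
    ]


def write_pav_table(path: str | Path, pavs: Sequence[PavEvent]) -> None:
    pd.DataFrame(
        [{c: getattr(p, c) for c in _PAV_COLUMNS} for p in pavs], columns=_PAV_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x conditions TSV with a gene_id index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated gene ids")
    return df


def write_expression(path: str | Path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_pwm(path: str | Path) -> Pwm:
    """Read a PWM from a MEME-minimal motif file or a 4 x w count TSV.

    The TSV dialect has rows A, C, G, T (first column the base label) and
    one column per motif position.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith("MEME version"):
        motif = motifs.parse(_io.StringIO(text), "minimal")[0]
        counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float)
        bg = motif.background
        background = np.array([bg[b] for b in "ACGT"], dtype=float)
        return Pwm(motif_id=motif.name, counts=counts, background=background)
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    if list(df.index) != list("ACGT"):
        raise ValueError(f"{path}: count table rows must be A, C, G, T")
    return Pwm(motif_id=Path(path).stem, counts=df.to_numpy(dtype=float))


def write_pwm_meme(path: str | Path, pwm: Pwm) -> None:
    counts = pwm.counts
    nsites = counts.sum(axis=0)
    nsites_val = int(round(nsites[0])) if len(nsites) else 0
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(
                f"{b} {pwm.background[i]:.5f}" for i, b in enumerate("ACGT")
            )
            + "\n\n"
        )
        fh.write(f"MOTIF {pwm.motif_id}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {nsites_val} E= 0\n"
        )
        for j in range(pwm.width):
            fh.write(" ".join(f"{freqs[i, j]:.6f}" for i in range(4)) + "\n")


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column gene -> GO term TSV (one pair per line, repeated genes ok)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, []).append(term)
    return out


def write_go_map(path: str | Path, go_map: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for gene in go_map:
            for term in go_map[gene]:
                fh.write(f"{gene}\t{term}\n")
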