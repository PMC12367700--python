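"""Structural-variation context of gene loci.

Relates transposable-element (TE) features and presence/absence-variation
(PAV) intervals to gene loci, and assigns simplified duplication modes
(tandem / proximal / dispersed / singleton) from homolog pairs and gene
rank along chromosomes. All coordinates are 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneLocus",
    "TEFeature",
    "PavEvent",
    "classify_te_position",
    "tally_te_classes",
    "pav_gene_overlap",
    "classify_duplication",
]


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end (half-open)")


@dataclass(frozen=True)
class TEFeature:
    chrom: str
    start: int
    end: int
    strand: str
    code: str  # three-letter TE classification code


@dataclass(frozen=True)
class PavEvent:
    accession_id: str
    chrom: str
    start: int
    end: int
    state: str  # insertion | deletion

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_te_position(
    te: TEFeature,
    gene: GeneLocus,
    window_bp: int = 2000,
    strand_aware: bool = True,
) -> str:
    """Position of a TE relative to a gene: upstream / genic / downstream / none.

    A TE overlapping the gene body is genic regardless of flank overlap.
    Flank labels follow the gene's 5'/3' orientation when ``strand_aware``
    (the default); with ``strand_aware=False`` the left flank is always
    upstream. Both features must be on the same chromosome (caller checks).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if _overlap(te.start, te.end, gene.start, gene.end) > 0:
        return "genic"
    left = _overlap(te.start, te.end, gene.start - window_bp, gene.start) > 0
    right = _overlap(te.start, te.end, gene.end, gene.end + window_bp) > 0
    if not left and not right:
        return "none"
    minus = strand_aware and gene.strand == "-"
    if left and right:  # straddles without touching the body: impossible, but be total
        return "genic"
    if left:
        return "downstream" if minus else "upstream"
    return "upstream" if minus else "downstream"


# Common superfamily names keyed by the three-letter code's last two letters,
# split by order (R = retrotransposon, D = DNA transposon).
_SUPERFAMILY_NAMES = {
    "LC": "Ty1-copia",
    "LG": "Ty3-gypsy",
    "LX": "LTR-unknown",
    "IX": "LINE",
    "SX": "SINE",
    "TC": "CACTA",
    "TM": "Mutator",
    "TH": "Harbinger",
    "TT": "Tc1-Mariner",
    "HH": "Helitron",
    "XX": "unclassified",
}


def te_code_classification(code: str) -> tuple[str, str]:
    """Map a three-letter TE code to (order, superfamily)."""
    if len(code) != 3:
        return "unknown", "unknown"
    order = {"R": "retrotransposon", "D": "DNA transposon"}.get(code[0].upper(), "unknown")
    suffix = code[1:3].upper()
    superfamily = _SUPERFAMILY_NAMES.get(suffix, suffix)
    return order, superfamily


def tally_te_classes(
    assignments: Iterable[tuple[TEFeature, str]],
) -> dict[str, Counter]:
    """Tally TE-gene assignments by position label, order and superfamily.

    ``assignments`` pairs each TE with its position label from
    :func:`classify_te_position`; 'none' labels are counted but excluded
    from the by-order/superfamily tallies of associated TEs.
    """
    by_position: Counter = Counter()
    by_order: Counter = Counter()
    by_superfamily: Counter = Counter()
    by_code: Counter = Counter()
    for te, label in assignments:
        by_position[label] += 1
        if label == "none":
            continue
        order, superfamily = te_code_classification(te.code)
        by_order[order] += 1
        by_superfamily[superfamily] += 1
        by_code[te.code if len(te.code) == 3 else "unknown"] += 1
    return {
        "position": by_position,
        "order": by_order,
        "superfamily": by_superfamily,
        "code": by_code,
    }


def pav_gene_overlap(
    pavs: Sequence[PavEvent], genes: Sequence[GeneLocus]
) -> pd.DataFrame:
    """Overlaps between PAV intervals and gene loci on the reference.

    One row per overlapping (gene, PAV) pair with the overlap length in bp;
    half-open arithmetic, so intervals that merely touch do not overlap.
    """
    rows = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for pav in pavs:
        for gene in by_chrom.get(pav.chrom, ()):
            ov = _overlap(pav.start, pav.end, gene.start, gene.end)
            if ov > 0:
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "accession_id": pav.accession_id,
                        "state": pav.state,
                        "overlap_bp": ov,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "accession_id", "state", "overlap_bp"])


def classify_duplication(
    genes: Sequence[GeneLocus],
    homolog_pairs: Iterable[tuple[str, str]],
    proximal_max_intervening: int = 10,
) -> dict[str, str]:
    """Simplified duplication-mode classification.

    Genes are ranked along each chromosome by start coordinate. A gene with
    no homolog is a singleton. Among its homologs, a gene takes the closest
    qualifying label: tandem when some homolog is rank-adjacent on the same
    chromosome (0 intervening genes), proximal when within
    ``proximal_max_intervening`` intervening genes, else dispersed.
    Whole-genome/segmental duplicates are not separated out (collinearity
    blocks are out of scope here) and fall into the dispersed class.
    """
    rank: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        for i, g in enumerate(sorted(gs, key=lambda x: (x.start, x.gene_id))):
            rank[g.gene_id] = (chrom, i)
    partners: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for a, b in homolog_pairs:
        if a not in partners or b not in partners:
            raise ValueError(f"homolog pair ({a}, {b}) references unknown gene")
        if a == b:
            continue
        partners[a].add(b)
        partners[b].add(a)
    labels: dict[str, str] = {}
    for gene_id, homs in partners.items():
        if not homs:
            labels[gene_id] = "singleton"
            continue
        best = "dispersed"
        chrom, r = rank[gene_id]
        for h in homs:
            h_chrom, h_r = rank[h]
            if h_chrom != chrom:
                continue
            intervening = abs(h_r - r) - 1
            if intervening == 0:
                best = "tandem"
                break
            if intervening <= proximal_max_intervening:
                best = "proximal"
        labels[gene_id] = best
    return labels
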