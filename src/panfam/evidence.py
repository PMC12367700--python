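"""Candidate gene identification evidence.

Parses the two tabular evidence dialects used when screening a proteome for
a domain-defined gene family — the HMMER per-domain table (domtblout) and
12-column tabular protein homology hits — applies the joint acceptance
thresholds (domain E-value and score, homology E-value and query coverage),
and computes the physicochemical protein properties typically reported for
family members (MW, pI, GRAVY, aliphatic and instability indices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "DomainHit",
    "HomologyHit",
    "ProteinProperties",
    "parse_domtblout",
    "parse_homology_tab",
    "filter_candidates",
    "protein_properties",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DomainHit:
    query_id: str  # the protein searched
    domain_name: str  # the profile HMM
    evalue: float  # per-domain independent E-value
    score: float  # per-domain bit score
    ali_from: int  # 1-based inclusive alignment coordinates on the protein
    ali_to: int


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    evalue: float
    bitscore: float
    q_start: int  # 1-based inclusive, normalized so q_start <= q_end
    q_end: int
    query_len: int

    @property
    def query_coverage(self) -> float:
        return (self.q_end - self.q_start + 1) / self.query_len


@dataclass(frozen=True)
class ProteinProperties:
    length_aa: int
    molecular_weight: float
    pI: float
    gravy: float
    aliphatic_index: float
    instability_index: float


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER per-domain tabular file (domtblout dialect).

    Lines starting with '#' are skipped. The protein is the target (first
    column), the profile the query; the per-domain independent E-value and
    bit score (columns 13-14) carry the filtering evidence.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 whitespace-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    query_id=fields[0],
                    domain_name=fields[3],
                    evalue=float(fields[12]),
                    score=float(fields[13]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def parse_homology_tab(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[HomologyHit]:
    """Parse 12-column tabular homology hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Query lengths are supplied separately so coverage can be computed; a
    query without a length entry is an error. Minus-orientation coordinates
    are normalized so q_start <= q_end.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            qid = fields[0]
            if qid not in query_lengths:
                raise ValueError(f"{path}:{lineno}: no length entry for query {qid!r}")
            try:
                q_start, q_end = int(fields[6]), int(fields[7])
                if q_start > q_end:
                    q_start, q_end = q_end, q_start
                hit = HomologyHit(
                    query_id=qid,
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    q_start=q_start,
                    q_end=q_end,
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_len=int(query_lengths[qid]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def filter_candidates(
    domain_hits: Iterable[DomainHit],
    homology_hits: Iterable[HomologyHit],
    evalue_dom: float = 1e-5,
    min_score: float = 20.0,
    evalue_hom: float = 1e-10,
    min_qcov: float = 0.70,
    require_both: bool = True,
) -> set[str]:
    """Accepted protein ids under the joint evidence thresholds.

    A protein passes the domain filter with at least one domain hit at
    E <= ``evalue_dom`` and score >= ``min_score``, and the homology filter
    with at least one hit at E <= ``evalue_hom`` and query coverage >=
    ``min_qcov``. By default both filters are required (AND);
    ``require_both=False`` accepts either (OR).
    """
    dom_pass = {
        h.query_id
        for h in domain_hits
        if h.evalue <= evalue_dom and h.score >= min_score
    }
    hom_pass = {
        h.query_id
        for h in homology_hits
        if h.evalue <= evalue_hom and h.query_coverage >= min_qcov
    }
    return dom_pass & hom_pass if require_both else dom_pass | hom_pass


# mole-percent weights of the aliphatic index (Ikai 1980)
_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}


def protein_properties(seq: str) -> ProteinProperties:
    """Physicochemical properties of a protein sequence.

    MW from average monomer masses minus one water per peptide bond; GRAVY
    as the mean Kyte-Doolittle hydropathy; aliphatic index as
    X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu) over mole-percent composition;
    pI by bisection of the Bjellqvist net-charge function; instability
    index from the Guruprasad dipeptide weights.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    analysis = ProteinAnalysis(seq)
    n = len(seq)
    aliphatic = sum(
        100.0 * seq.count(aa) / n * w for aa, w in _ALIPHATIC_WEIGHTS.items()
    )
    ip = IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        charge = ip.charge_at_pH(mid)
        if abs(charge) < 1e-6:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    pI = (lo + hi) / 2.0
    return ProteinProperties(
        length_aa=n,
        molecular_weight=analysis.molecular_weight(),
        pI=pI,
        gravy=analysis.gravy(),
        aliphatic_index=aliphatic,
        instability_index=analysis.instability_index() if n >= 2 else float("nan"),
    )
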