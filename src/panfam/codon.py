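"""Codon usage bias suite.

Per-gene statistics commonly used to characterise codon bias in plant gene
families: relative synonymous codon usage (RSCU), Wright's effective number
of codons (ENC), the codon adaptation index (CAI), GC content overall and at
synonymously variable third positions (GC3s), third-position nucleotide
composition (T3s/C3s/A3s/G3s), parity-rule-2 (PR2) coordinates, the expected
ENC-vs-GC3s neutrality curve, and identification of optimal codons from
ENC-stratified high/low bias gene sets.

All statistics operate on :class:`CodonCounts` produced by
:func:`count_codons`, so every downstream value is invariant to how the CDS
was read in.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonCounts",
    "CodonUsageProfile",
    "GENETIC_CODE",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "count_codons",
    "rscu",
    "enc",
    "enc_expected",
    "cai",
    "third_position_composition",
    "codon_profile",
    "optimal_codons",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, standard nuclear code, sense codons only
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: amino acid -> tuple of synonymous codons (all 20, incl. Met/Trp singletons)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: amino acids whose family has a single codon (excluded from RSCU/CAI/GC3s)
SINGLE_CODON_AA = frozenset(
    aa for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) == 1
)

_VALID_BASES = frozenset("ACGT")


@dataclass
class CodonCounts:
    """Sense-codon counts for one coding sequence.

    Stop codons are never counted; codons containing ambiguous bases are
    skipped and tallied in ``n_skipped``.
    """

    gene_id: str
    counts: Counter = field(default_factory=Counter)
    n_codons: int = 0
    n_skipped: int = 0


@dataclass
class CodonUsageProfile:
    """Per-gene codon usage summary (one row of the suite's output table)."""

    gene_id: str
    enc: float
    cai: float
    gc: float
    gc3s: float
    t3s: float
    c3s: float
    a3s: float
    g3s: float
    pr2_x: float  # G3/(G3+C3)
    pr2_y: float  # A3/(A3+T3)
    rscu: dict[str, float]


def count_codons(cds: str, gene_id: str = "") -> CodonCounts:
    """Count sense codons of an in-frame CDS.

    The terminal stop codon (if present) is excluded; an internal stop or a
    length not divisible by 3 raises ``ValueError``. Codons with non-ACGT
    characters are skipped and counted separately.
    """
    cds = cds.upper()
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds)} of {gene_id!r} is not a positive multiple of 3"
        )
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out = CodonCounts(gene_id=gene_id)
    for i, codon in enumerate(codons):
        if not _VALID_BASES.issuperset(codon):
            out.n_skipped += 1
            continue
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {i} in {gene_id!r}")
        out.counts[codon] += 1
        out.n_codons += 1
    return out


def rscu(counts: CodonCounts | Counter) -> dict[str, float]:
    """Relative synonymous codon usage.

    RSCU_c = observed count / mean count over the codon's synonymous family.
    Families with zero total usage are absent from the result; single-codon
    families (Met, Trp) are excluded.
    """
    c = counts.counts if isinstance(counts, CodonCounts) else counts
    out: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa in SINGLE_CODON_AA:
            continue
        total = sum(c.get(codon, 0) for codon in family)
        if total == 0:
            continue
        mean = total / len(family)
        for codon in family:
            out[codon] = c.get(codon, 0) / mean
    return out


# ENC degeneracy classes: number of families per synonymous-family size.
_ENC_CLASS_FAMILIES = {2: 9, 3: 1, 4: 5, 6: 3}
_ENC_CLASS_FAMILIES_SPLIT6 = {2: 12, 3: 1, 4: 8}


def enc(counts: CodonCounts | Counter, split_sixfold: bool = False) -> float:
    """Wright's effective number of codons.

    Per family with n > 1 codons observed, the codon homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); class means over family sizes
    s in {2, 3, 4, 6} enter ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6. A missing
    three-fold class mean (Ile unobserved) is imputed as the average of the
    two- and four-fold means. Families with F = 0 are excluded from their
    class mean. The result is clamped to [20, 61]; NaN when no two-fold or
    four-fold family is computable.

    With ``split_sixfold`` the Leu/Ser/Arg families are split into 2+4
    sub-families (ENC = 2 + 12/F2 + 1/F3 + 8/F4).
    """
    c = counts.counts if isinstance(counts, CodonCounts) else counts
    families: list[tuple[int, tuple[str, ...]]] = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa in SINGLE_CODON_AA:
            continue
        if split_sixfold and len(family) == 6:
            # split by first two bases: the 4-fold box shares a prefix
            prefixes = Counter(f[:2] for f in family)
            four_prefix = next(p for p, k in prefixes.items() if k == 4)
            four = tuple(f for f in family if f[:2] == four_prefix)
            two = tuple(f for f in family if f[:2] != four_prefix)
            families.append((2, two))
            families.append((4, four))
        else:
            families.append((len(family), family))

    f_by_class: dict[int, list[float]] = {}
    for size, family in families:
        n = sum(c.get(codon, 0) for codon in family)
        if n <= 1:
            continue
        p2 = sum((c.get(codon, 0) / n) ** 2 for codon in family)
        f_hat = (n * p2 - 1) / (n - 1)
        if f_hat > 0:
            f_by_class.setdefault(size, []).append(f_hat)

    class_sizes = _ENC_CLASS_FAMILIES_SPLIT6 if split_sixfold else _ENC_CLASS_FAMILIES
    means = {s: float(np.mean(v)) for s, v in f_by_class.items()}
    if 2 not in means or 4 not in means:
        return float("nan")
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2.0
    value = 2.0
    for size, n_fam in class_sizes.items():
        if size == 6 and 6 not in means:
            # no six-fold family observed: approximate by the four-fold mean
            means[6] = means[4]
        value += n_fam / means[size]
    return float(min(61.0, max(20.0, value)))


def enc_expected(gc3s: float) -> float:
    """Wright's expected ENC under mutation pressure alone.

    ENC* = 2 + s + 29 / (s^2 + (1 - s)^2), the reference curve of the
    ENC-vs-GC3s neutrality plot.
    """
    s = float(gc3s)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def relative_adaptiveness(reference: Iterable[CodonCounts | Counter]) -> dict[str, float]:
    """Codon relative adaptiveness w from a pooled reference gene set.

    Reference counts are pooled; zero counts are replaced by 0.5 before
    computing RSCU so that no codon gets w = 0. w_c = RSCU_c / max RSCU in
    the codon's family.
    """
    pooled: Counter = Counter()
    n_refs = 0
    for ref in reference:
        c = ref.counts if isinstance(ref, CodonCounts) else ref
        pooled.update(c)
        n_refs += 1
    if n_refs == 0:
        raise ValueError("reference gene set is empty")
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa in SINGLE_CODON_AA:
            continue
        for codon in family:
            if pooled.get(codon, 0) == 0:
                pooled[codon] = 0.5
    ref_rscu = rscu(pooled)
    w: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa in SINGLE_CODON_AA:
            continue
        fam_max = max(ref_rscu[codon] for codon in family)
        for codon in family:
            w[codon] = ref_rscu[codon] / fam_max
    return w


def cai(counts: CodonCounts | Counter, reference: Iterable[CodonCounts | Counter]) -> float:
    """Codon adaptation index against a reference gene set.

    Geometric mean of the relative adaptiveness w over the gene's codons,
    excluding Met, Trp and stops. NaN when the gene has no scorable codon.
    """
    w = relative_adaptiveness(reference)
    c = counts.counts if isinstance(counts, CodonCounts) else counts
    log_sum = 0.0
    n = 0
    for codon, k in c.items():
        if codon not in w:  # Met/Trp
            continue
        log_sum += k * math.log(w[codon])
        n += k
    if n == 0:
        return float("nan")
    return float(math.exp(log_sum / n))


def third_position_composition(counts: CodonCounts | Counter) -> dict[str, float]:
    """Third-position composition over synonymously variable codons.

    Met and Trp codons (and stops, never counted) are excluded. Returns the
    four base fractions, GC3s, and the PR2 coordinates
    pr2_x = G3/(G3+C3), pr2_y = A3/(A3+T3). Components with a zero
    denominator are NaN.
    """
    c = counts.counts if isinstance(counts, CodonCounts) else counts
    tally = {b: 0 for b in "ACGT"}
    for codon, k in c.items():
        aa = GENETIC_CODE.get(codon)
        if aa is None or aa in SINGLE_CODON_AA:
            continue
        tally[codon[2]] += k
    total = sum(tally.values())
    a3, c3, g3, t3 = tally["A"], tally["C"], tally["G"], tally["T"]
    nan = float("nan")
    return {
        "t3s": t3 / total if total else nan,
        "c3s": c3 / total if total else nan,
        "a3s": a3 / total if total else nan,
        "g3s": g3 / total if total else nan,
        "gc3s": (g3 + c3) / total if total else nan,
        "pr2_x": g3 / (g3 + c3) if (g3 + c3) else nan,
        "pr2_y": a3 / (a3 + t3) if (a3 + t3) else nan,
    }


def gc_content(counts: CodonCounts | Counter) -> float:
    """Overall G+C fraction across all three positions of counted codons."""
    c = counts.counts if isinstance(counts, CodonCounts) else counts
    gc = 0
    total = 0
    for codon, k in c.items():
        gc += k * sum(1 for b in codon if b in "GC")
        total += 3 * k
    return gc / total if total else float("nan")


def codon_profile(
    counts: CodonCounts,
    reference: Sequence[CodonCounts] | None = None,
    split_sixfold: bool = False,
) -> CodonUsageProfile:
    """Assemble the full per-gene profile; CAI is NaN without a reference."""
    third = third_position_composition(counts)
    return CodonUsageProfile(
        gene_id=counts.gene_id,
        enc=enc(counts, split_sixfold=split_sixfold),
        cai=cai(counts, reference) if reference else float("nan"),
        gc=gc_content(counts),
        gc3s=third["gc3s"],
        t3s=third["t3s"],
        c3s=third["c3s"],
        a3s=third["a3s"],
        g3s=third["g3s"],
        pr2_x=third["pr2_x"],
        pr2_y=third["pr2_y"],
        rscu=rscu(counts),
    )


def profiles_to_frame(profiles: Iterable[CodonUsageProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "gene_id": p.gene_id,
                "enc": p.enc,
                "cai": p.cai,
                "gc": p.gc,
                "gc3s": p.gc3s,
                "t3s": p.t3s,
                "c3s": p.c3s,
                "a3s": p.a3s,
                "g3s": p.g3s,
                "pr2_x": p.pr2_x,
                "pr2_y": p.pr2_y,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def optimal_codons(
    counts_list: Sequence[CodonCounts],
    enc_values: Mapping[str, float] | None = None,
    tail: float = 0.10,
    delta_min: float = 0.3,
) -> pd.DataFrame:
    """Optimal codons from ENC-stratified gene sets.

    Genes are ranked by ENC; the lowest-ENC ``tail`` fraction is the
    high-bias ("high-expression") set and the highest-ENC tail the low-bias
    set. RSCU is computed on the pooled counts of each set, and a codon is
    flagged optimal when RSCU_high > 1, RSCU_low < 1 and
    RSCU_high - RSCU_low >= ``delta_min``.
    """
    if enc_values is None:
        enc_values = {c.gene_id: enc(c) for c in counts_list}
    scored = [(c, enc_values[c.gene_id]) for c in counts_list]
    scored = [(c, e) for c, e in scored if not math.isnan(e)]
    if len(scored) < 10:
        raise ValueError("need at least 10 genes with defined ENC")
    n_tail = int(len(scored) * tail)
    if n_tail < 1:
        raise ValueError(f"tail fraction {tail} selects no genes out of {len(scored)}")
    scored.sort(key=lambda ce: (ce[1], ce[0].gene_id))
    high = Counter()
    low = Counter()
    for c, _ in scored[:n_tail]:
        high.update(c.counts)
    for c, _ in scored[-n_tail:]:
        low.update(c.counts)
    rscu_high = rscu(high)
    rscu_low = rscu(low)
    rows = []
    for aa, family in sorted(SYNONYMOUS_FAMILIES.items()):
        if aa in SINGLE_CODON_AA:
            continue
        for codon in family:
            rh = rscu_high.get(codon, float("nan"))
            rl = rscu_low.get(codon, float("nan"))
            delta = rh - rl
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "rscu_high": rh,
                    "rscu_low": rl,
                    "delta_rscu": delta,
                    "is_optimal": bool(
                        rh > 1.0 and rl < 1.0 and delta >= delta_min
                    ),
                }
            )
    return pd.DataFrame(rows).set_index("codon")
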