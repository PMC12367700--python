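"""Selection-pressure analysis for ortholog pairs.

Ka/Ks is estimated with the approximate counting method of Nei & Gojobori
(1986): synonymous/nonsynonymous site fractions per codon averaged over the
two sequences, difference counts averaged over all shortest substitution
pathways between differing codons (pathways through stop codons excluded),
and a Jukes-Cantor multiple-hit correction on both proportions. The
core-vs-dispensable contrast uses a Mann-Whitney U test with an exact
enumeration branch for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .codon import GENETIC_CODE, STOP_CODONS

__all__ = ["KaKsResult", "ng86", "codon_align", "mann_whitney", "kaks_group_compare"]

_BASES = "ACGT"


@dataclass
class KaKsResult:
    """Site and difference counts plus corrected rates for one CDS pair."""

    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    ps: float
    pn: float
    Ks: float  # NaN when the correction is undefined (p >= 3/4)
    Ka: float
    ratio: float  # Ka/Ks; NaN when Ks is 0 or undefined


def _codon_syn_fraction(codon: str) -> float:
    """Synonymous site count of one sense codon (0..3).

    At each position, the fraction of the three possible point changes that
    are synonymous; changes producing a stop codon count as nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (Sd, Nd) over shortest substitution pathways c1 -> c2.

    Pathways passing through a stop codon are excluded; if every ordering is
    blocked, all orderings are used with steps into/out of stops counted as
    nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            aa_cur = GENETIC_CODE.get(cur)
            aa_nxt = GENETIC_CODE.get(nxt)
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd_mean = sum(p[0] for p in paths) / len(paths)
    nd_mean = sum(p[1] for p in paths) / len(paths)
    return sd_mean, nd_mean


def ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for an aligned, gapless, in-frame CDS pair."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS pair must have equal lengths")
    if len(cds_a) == 0 or len(cds_a) % 3 != 0:
        raise ValueError("aligned length must be a positive multiple of 3")
    n_codons = len(cds_a) // 3
    S = Sd = Nd = 0.0
    for i in range(n_codons):
        ca = cds_a[3 * i : 3 * i + 3]
        cb = cds_b[3 * i : 3 * i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon within aligned CDS at codon {i}")
        S += (_codon_syn_fraction(ca) + _codon_syn_fraction(cb)) / 2.0
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    if math.isnan(Ka) or math.isnan(Ks) or Ks == 0.0:
        ratio = float("nan")
    else:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka, ratio=ratio)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def codon_align(cds_a: str, cds_b: str, protein_alignment=None) -> tuple[str, str]:
    """Codon-aware pairwise alignment of two CDS, gaps removed codon-wise.

    The protein sequences are aligned (semiglobal, same scoring as the
    clustering stage) and the alignment is back-translated; codon columns
    containing a gap in either sequence are dropped, yielding the gapless
    equal-length pair :func:`ng86` expects. Terminal stop codons are trimmed
    first.
    """
    from .cluster import get_aligner  # local import to avoid cycle

    def _trim(cds: str) -> str:
        if len(cds) % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")
        if cds[-3:].upper() in STOP_CODONS:
            return cds[:-3]
        return cds

    cds_a, cds_b = _trim(cds_a.upper()), _trim(cds_b.upper())
    prot_a = "".join(GENETIC_CODE[cds_a[i : i + 3]] for i in range(0, len(cds_a), 3))
    prot_b = "".join(GENETIC_CODE[cds_b[i : i + 3]] for i in range(0, len(cds_b), 3))
    if protein_alignment is None:
        protein_alignment = get_aligner().align(prot_a, prot_b)[0]
    ga, gb = str(protein_alignment[0]), str(protein_alignment[1])
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for col in range(len(ga)):
        a_gap, b_gap = ga[col] == "-", gb[col] == "-"
        if not a_gap and not b_gap:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
        if not a_gap:
            ia += 1
        if not b_gap:
            ib += 1
    return "".join(out_a), "".join(out_b)


def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """U for group a versus b, counting ties as 1/2."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of group assignments when both samples have
    at most 8 observations (handles ties); otherwise the normal
    approximation with tie and continuity corrections. Returns (U, p) where
    U is the statistic of ``group_a``.
    """
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    n, m = len(a), len(b)
    u_a = _u_statistic(a, b)
    if n <= 8 and m <= 8:
        pooled = a + b
        idx = range(n + m)
        u_lo = min(u_a, n * m - u_a)
        u_hi = n * m - u_lo
        count = 0
        total = 0
        for comb in combinations(idx, n):
            comb_set = set(comb)
            ga = [pooled[i] for i in comb]
            gb = [pooled[i] for i in idx if i not in comb_set]
            u = _u_statistic(ga, gb)
            if u_lo == u_hi:
                hit = True
            else:
                hit = u <= u_lo or u >= u_hi
            count += hit
            total += 1
        return u_a, count / total
    return u_a, _normal_approx_p(a, b, u_a)


def _normal_approx_p(a: Sequence[float], b: Sequence[float], u_a: float) -> float:
    """Two-sided normal approximation with tie and continuity corrections."""
    n, m = len(a), len(b)
    pooled = np.asarray(list(a) + list(b))
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if var == 0:
        return 1.0
    z = max((abs(u_a - n * m / 2.0) - 0.5) / math.sqrt(var), 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def kaks_group_compare(
    results: Mapping[str, KaKsResult],
    classes: Mapping[str, str],
    core_label: str = "core",
) -> dict[str, dict[str, float]]:
    """Core-vs-dispensable contrast of Ka, Ks and Ka/Ks.

    ``results`` maps orthogroup id -> per-orthogroup KaKsResult and
    ``classes`` maps orthogroup id -> occupancy label; dispensable pools the
    soft-core, shell and cloud labels. NaN values (undefined corrections,
    Ks = 0 ratios) are excluded per metric, with the exclusion count
    reported. Raises if either group is empty for a metric.
    """
    metrics = {"Ka": "Ka", "Ks": "Ks", "Ka/Ks": "ratio"}
    out: dict[str, dict[str, float]] = {}
    for name, attr in metrics.items():
        core_vals: list[float] = []
        disp_vals: list[float] = []
        n_excluded = 0
        for og, res in results.items():
            if og not in classes:
                continue
            v = getattr(res, attr)
            if math.isnan(v):
                n_excluded += 1
                continue
            (core_vals if classes[og] == core_label else disp_vals).append(v)
        if not core_vals or not disp_vals:
            raise ValueError(f"empty group for metric {name} after NA exclusion")
        u, p = mann_whitney(core_vals, disp_vals)
        out[name] = {
            "U": u,
            "p": p,
            "n_core": len(core_vals),
            "n_dispensable": len(disp_vals),
            "n_excluded": n_excluded,
            "median_core": float(np.median(core_vals)),
            "median_dispensable": float(np.median(disp_vals)),
        }
    return out
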