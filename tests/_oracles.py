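"""Independent reference implementations used only to validate the package.

Each oracle recomputes a quantity by direct enumeration or a
straight-from-the-formula transcription, sharing no logic with the
implementation under test (alignment scoring is the one shared primitive,
exercised separately).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

from panfam.cluster import pairwise_identity
from panfam.codon import GENETIC_CODE, STOP_CODONS


# ---------------------------------------------------------------------------
# greedy clustering oracle: direct transcription of the rules with explicit
# loops and its own bookkeeping
# ---------------------------------------------------------------------------

def greedy_cluster_oracle(records, min_identity=0.95, min_longer_cov=0.90, min_aln_len=100):
    """Partition as frozensets of gene ids, by the longest-first greedy rules."""
    order = sorted(records, key=lambda r: (-len(r.sequence), r.gene_id))
    cluster_reps = []  # (rep_record)
    cluster_members = []  # list of lists
    for rec in order:
        joined = False
        for i in range(len(cluster_reps)):
            rep = cluster_reps[i]
            ident, cov, alen = pairwise_identity(rep.sequence, rec.sequence)
            ok = (
                ident >= min_identity
                and cov >= min_longer_cov
                and alen >= min_aln_len
            )
            if ok:
                cluster_members[i].append(rec.gene_id)
                joined = True
                break
        if not joined:
            cluster_reps.append(rec)
            cluster_members.append([rec.gene_id])
    return {frozenset(m) for m in cluster_members}


# ---------------------------------------------------------------------------
# NG86 oracle: independent site and pathway enumeration
# ---------------------------------------------------------------------------

def _syn_sites_one_codon(codon):
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        n_syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # counts as nonsynonymous
            if GENETIC_CODE[mutant] == aa:
                n_syn += 1
        total += n_syn / 3.0
    return total


def ng86_counts_oracle(cds_a, cds_b):
    """(S, N, Sd, Nd) by exhaustive per-codon enumeration."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    S = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        S += (_syn_sites_one_codon(ca) + _syn_sites_one_codon(cb)) / 2.0
        positions = [j for j in range(3) if ca[j] != cb[j]]
        if not positions:
            continue
        paths = []
        blocked = []
        for order in itertools.permutations(positions):
            current = ca
            sd = nd = 0
            ok = True
            for j in order:
                following = current[:j] + cb[j] + current[j + 1 :]
                if following in STOP_CODONS:
                    ok = False
                if (
                    current not in STOP_CODONS
                    and following not in STOP_CODONS
                    and GENETIC_CODE[current] == GENETIC_CODE[following]
                ):
                    sd += 1
                else:
                    nd += 1
                current = following
            (paths if ok else blocked).append((sd, nd))
        use = paths or blocked
        Sd += sum(p[0] for p in use) / len(use)
        Nd += sum(p[1] for p in use) / len(use)
    N = len(cds_a) - S
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Mann-Whitney full-enumeration oracle
# ---------------------------------------------------------------------------

def mann_whitney_exact_oracle(a, b):
    """Two-sided p over all C(n+m, n) group assignments of the pooled data."""
    pooled = list(a) + list(b)
    n = len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(a, b)
    u_lo = min(u_obs, len(a) * len(b) - u_obs)
    u_hi = len(a) * len(b) - u_lo
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        in_a = set(combo)
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in in_a]
        u = u_of(ga, gb)
        if u_lo == u_hi or u <= u_lo or u >= u_hi:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# ENC straight-from-formula oracle
# ---------------------------------------------------------------------------

_FAMILIES_BY_AA = {}
for codon, aa in GENETIC_CODE.items():
    _FAMILIES_BY_AA.setdefault(aa, []).append(codon)


def enc_oracle(counts: Counter):
    f_values = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in _FAMILIES_BY_AA.items():
        size = len(codons)
        if size == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n <= 1:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            f_values[size].append(f)
    means = {s: sum(v) / len(v) for s, v in f_values.items() if v}
    if 2 not in means or 4 not in means:
        return float("nan")
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2
    if 6 not in means:
        means[6] = means[4]
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(61.0, max(20.0, value))


# ---------------------------------------------------------------------------
# PWM p-value oracle: enumerate all 4^w words under the background
# ---------------------------------------------------------------------------

def pwm_pvalues_oracle(pwm, granularity=1e-3):
    """{quantized integer score: P(score >= that)} over all 4^w words."""
    lo = pwm.log_odds()
    w = pwm.width
    q = np.rint(lo / granularity).astype(int)
    entries = []
    for word in itertools.product(range(4), repeat=w):
        score = sum(int(q[word[j], j]) for j in range(w))
        prob = 1.0
        for j in range(w):
            prob *= pwm.background[word[j]]
        entries.append((score, prob))
    entries.sort(reverse=True)
    out = {}
    acc = 0.0
    i = 0
    while i < len(entries):
        score = entries[i][0]
        while i < len(entries) and entries[i][0] == score:
            acc += entries[i][1]
            i += 1
        out[score] = acc
    return out


# ---------------------------------------------------------------------------
# hypergeometric enrichment oracle: exact combinatorial sum
# ---------------------------------------------------------------------------

def hypergeom_upper_tail_oracle(k, N, K, n):
    total = math.comb(N, n)
    acc = 0
    for kk in range(k, min(K, n) + 1):
        acc += math.comb(K, kk) * math.comb(N - K, n - kk)
    return acc / total
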