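"""Regulatory-network construction around focal transcription factors.

Three ingredients: Pearson co-expression edges between focal genes and
candidate targets (r and two-sided t-test p thresholds, strict
inequalities), a position-weight-matrix promoter scanner with exact
log-odds-score p-values computed by dynamic programming over the
discretized score distribution, and hypergeometric GO-term enrichment with
Benjamini-Hochberg correction. Targets kept in the assembled network must
both pass the correlation filter and carry at least one motif hit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoexpressionEdge",
    "Pwm",
    "MotifHit",
    "pearson_edges",
    "pwm_scan",
    "enrich",
    "assemble_network",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CoexpressionEdge:
    source: str  # focal gene
    target: str
    r: float
    p: float


@dataclass
class Pwm:
    """Position count matrix with background model and pseudocount."""

    motif_id: str
    counts: np.ndarray  # 4 x w, rows A C G T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A, C, G, T)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2 odds of pseudocount-regularized frequencies vs background."""
        col_tot = self.counts.sum(axis=0)
        freqs = (self.counts + self.pseudocount) / (col_tot + 4 * self.pseudocount)
        return np.log2(freqs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    offset: int  # 0-based on the forward strand
    strand: str
    score: float  # log2 odds, quantized to the scan granularity
    p: float


def pearson_edges(
    expr: pd.DataFrame,
    focal_genes: Iterable[str],
    r_min: float = 0.9,
    p_max: float = 0.01,
) -> list[CoexpressionEdge]:
    """Co-expression edges from each focal gene to every non-focal gene.

    Pearson r over the condition columns; two-sided p from the t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom. An edge is kept
    iff r > r_min and p < p_max (both strict). Zero-variance rows are
    skipped with a warning.
    """
    n_cond = expr.shape[1]
    if n_cond < 3:
        raise ValueError("need at least 3 condition columns")
    focal = [g for g in focal_genes if g in expr.index]
    targets = [g for g in expr.index if g not in set(focal)]
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = {expr.index[i] for i in np.flatnonzero(sd == 0)}
    if flat:
        warnings.warn(f"skipping {len(flat)} zero-variance gene(s)")
    focal = [g for g in focal if g not in flat]
    targets = [g for g in targets if g not in flat]
    if not focal or not targets:
        return []
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True).clip(min=1e-300)
    loc = {g: i for i, g in enumerate(expr.index)}
    F = Z[[loc[g] for g in focal]]
    T = Z[[loc[g] for g in targets]]
    R = (F @ T.T) / n_cond
    R = np.clip(R, -1.0, 1.0)
    df = n_cond - 2
    with np.errstate(divide="ignore"):
        tstat = R * np.sqrt(df / np.maximum(1.0 - R**2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(tstat), df)
    edges: list[CoexpressionEdge] = []
    for i, src in enumerate(focal):
        for j, tgt in enumerate(targets):
            r, p = float(R[i, j]), float(P[i, j])
            if r > r_min and p < p_max:
                edges.append(CoexpressionEdge(src, tgt, r, p))
    return edges


def _score_distribution(int_scores: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact distribution of the integer-quantized score under background.

    Returns (probabilities, offset) where probabilities[i] is the mass of
    integer score i + offset. Computed by per-column convolution.
    """
    w = int_scores.shape[1]
    lo = int(int_scores.min(axis=0).sum())
    hi = int(int_scores.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # start with the first column
    cur_lo = int(int_scores[:, 0].min())
    cur = np.zeros(int(int_scores[:, 0].max()) - cur_lo + 1)
    for b in range(4):
        cur[int(int_scores[b, 0]) - cur_lo] += background[b]
    for col in range(1, w):
        col_lo = int(int_scores[:, col].min())
        col_hi = int(int_scores[:, col].max())
        nxt = np.zeros(len(cur) + (col_hi - col_lo))
        for b in range(4):
            shift = int(int_scores[b, col]) - col_lo
            nxt[shift : shift + len(cur)] += background[b] * cur
        cur = nxt
        cur_lo += col_lo
    dist[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return dist, lo


def pwm_scan(
    promoters: Mapping[str, str],
    pwm: Pwm,
    p_max: float = 1e-4,
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Scan promoters on both strands for PWM matches with p <= ``p_max``.

    Scores are log2 odds against the background, quantized to
    ``granularity`` bits; the p-value of a score is the exact probability
    of an equal-or-higher quantized score for a random background word,
    obtained from the dynamic-programming score distribution. Reverse-
    strand hits are reported at their forward-strand offset. Promoters
    shorter than the motif width are skipped with a warning.
    """
    lo_matrix = pwm.log_odds()
    w = pwm.width
    int_scores = np.rint(lo_matrix / granularity).astype(np.int64)
    dist, offset = _score_distribution(int_scores, pwm.background)
    # upper-tail probabilities: pval_of[i] = P(score >= i + offset)
    tail = np.cumsum(dist[::-1])[::-1]

    def pval(q: int) -> float:
        i = q - offset
        if i < 0:
            return 1.0
        if i >= len(tail):
            return 0.0
        return float(tail[i])

    hits: list[MotifHit] = []
    for pid, seq in promoters.items():
        seq = seq.upper()
        if len(seq) < w:
            warnings.warn(f"promoter {pid} shorter than motif width {w}; skipped")
            continue
        for strand in "+-":
            s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
            enc = np.fromiter(
                (_BASE_INDEX.get(ch, 4) for ch in s), dtype=np.int64, count=len(s)
            )
            windows = np.lib.stride_tricks.sliding_window_view(enc, w)
            valid = (windows < 4).all(axis=1)
            cols = np.arange(w)
            padded = np.vstack([int_scores, np.full((1, w), np.iinfo(np.int32).min // w)])
            scores = padded[windows, cols].sum(axis=1)
            for off in np.flatnonzero(valid):
                q = int(scores[off])
                p = pval(q)
                if p <= p_max:
                    fwd_off = off if strand == "+" else len(seq) - w - off
                    hits.append(
                        MotifHit(
                            promoter_id=pid,
                            offset=int(fwd_off),
                            strand=strand,
                            score=q * granularity,
                            p=p,
                        )
                    )
    hits.sort(key=lambda h: (h.promoter_id, h.offset, h.strand))
    return hits


def enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail GO-term enrichment with BH correction.

    ``term_map`` maps gene -> iterable of term ids. Every term annotated in
    the background is tested; p = P(X >= k) with X ~ Hypergeom(N, K, n).
    Rows are sorted by p.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in term_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    N, n = len(bg), len(fg)
    rows = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


def assemble_network(
    edges: Sequence[CoexpressionEdge],
    hits: Sequence[MotifHit],
    cluster_labels: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Node/edge tables for targets passing both network criteria.

    A target is retained iff it has a co-expression edge from a focal gene
    AND at least one motif hit in its promoter. Returns (nodes, edges,
    per-cluster target counts); clusters come from ``cluster_labels`` when
    given.
    """
    with_hit = {h.promoter_id for h in hits}
    kept = [e for e in edges if e.target in with_hit]
    edge_df = pd.DataFrame(
        [{"source": e.source, "target": e.target, "r": e.r, "p": e.p} for e in kept],
        columns=["source", "target", "r", "p"],
    )
    nodes = []
    for name, role in [(e.source, "focal") for e in kept] + [
        (e.target, "target") for e in kept
    ]:
        nodes.append((name, role))
    node_df = (
        pd.DataFrame(nodes, columns=["node", "role"]).drop_duplicates().reset_index(drop=True)
        if nodes
        else pd.DataFrame(columns=["node", "role"])
    )
    if cluster_labels is not None and len(node_df):
        node_df["cluster"] = [cluster_labels.get(n, -1) for n in node_df["node"]]
        target_mask = node_df["role"] == "target"
        per_cluster = node_df.loc[target_mask].groupby("cluster")["node"].count()
    else:
        per_cluster = pd.Series(dtype=int)
    return node_df, edge_df, per_cluster
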