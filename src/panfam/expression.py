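"""Expression summarization and fuzzy time-course clustering.

Tissue panels are summarized as per-gene min-max-normalized profiles and
per-group raw-FPKM means. Time-course matrices are filtered (mean FPKM
below threshold dropped), row-standardized, and partitioned with fuzzy
c-means — the soft-clustering algorithm behind Mfuzz-style time-series
analysis — using Euclidean distance and a configurable fuzzifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FuzzyClusteringResult",
    "tissue_summary",
    "filter_and_standardize",
    "fuzzy_cmeans",
    "cluster_membership_table",
]


@dataclass
class FuzzyClusteringResult:
    """Soft partition of standardized expression profiles.

    ``memberships`` is genes x clusters (rows sum to 1), ``centers`` is
    clusters x conditions, ``hard_labels`` the per-gene argmax cluster.
    """

    memberships: pd.DataFrame
    centers: pd.DataFrame
    fuzzifier: float
    hard_labels: pd.Series
    n_iterations: int
    objective_trace: list[float] = field(default_factory=list)


def tissue_summary(
    expr: pd.DataFrame, group_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-gene min-max normalized matrix and optional per-group means.

    Min-max scales each gene's profile to [0, 1] across conditions;
    constant rows map to all zeros. Group means (e.g., per orthogroup or
    per conservation class) are computed on the raw FPKM values.
    """
    if (expr.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    mn = expr.min(axis=1)
    rng = expr.max(axis=1) - mn
    safe = rng.replace(0, np.nan)
    normalized = expr.sub(mn, axis=0).div(safe, axis=0).fillna(0.0)
    group_means = None
    if group_map is not None:
        labels = pd.Series(
            {g: group_map[g] for g in expr.index if g in group_map}, name="group"
        )
        if len(labels):
            group_means = expr.loc[labels.index].groupby(labels).mean()
    return normalized, group_means


def filter_and_standardize(
    expr: pd.DataFrame, min_mean: float = 10.0
) -> pd.DataFrame:
    """Drop low-expression genes and z-score the survivors per gene.

    Rows with mean FPKM < ``min_mean`` are removed (a mean of exactly
    ``min_mean`` is kept). Surviving rows are standardized to mean 0 and
    (ddof=1) standard deviation 1 across conditions; zero-variance rows
    cannot be standardized and are dropped with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    kept = expr.loc[expr.mean(axis=1) >= min_mean]
    sd = kept.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance gene(s) that cannot be standardized"
        )
        kept = kept.loc[~flat]
        sd = sd.loc[~flat]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd, axis=0)


def _fcm_once(
    X: np.ndarray, k: int, m: float, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    exponent = 2.0 / (m - 1.0)
    trace: list[float] = []
    eps = 1e-12
    u = np.full((n, k), 1.0 / k)
    for iteration in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, eps)
        inv = d2 ** (-exponent / 2.0)  # d^(-2/(m-1))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        trace.append(float((um * d2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return u, centers, iteration, trace


def fuzzy_cmeans(
    std: pd.DataFrame,
    k: int = 10,
    m: float = 1.25,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_init: int = 5,
) -> FuzzyClusteringResult:
    """Fuzzy c-means with Euclidean distance.

    Memberships follow u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1)); centers
    are the u^m-weighted means. Each of ``n_init`` restarts draws k
    distinct rows as initial centers (seeded substreams), runs until the
    largest center coordinate shift falls below ``tol`` or ``max_iter``
    rounds, and the restart with the lowest final objective
    sum(u^m d^2) is kept. Within a run the recorded objective trace is
    non-increasing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > std.shape[0]:
        raise ValueError(f"k={k} exceeds the {std.shape[0]} available rows")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    X = std.to_numpy(dtype=float)
    best = None
    for ss in np.random.SeedSequence(seed).spawn(n_init):
        u, centers, iteration, trace = _fcm_once(
            X, k, m, np.random.default_rng(ss), max_iter, tol
        )
        if best is None or trace[-1] < best[3][-1]:
            best = (u, centers, iteration, trace)
    u, centers, iteration, trace = best
    labels = pd.Series(np.argmax(u, axis=1), index=std.index, name="cluster")
    return FuzzyClusteringResult(
        memberships=pd.DataFrame(
            u, index=std.index, columns=[f"cluster_{j}" for j in range(k)]
        ),
        centers=pd.DataFrame(
            centers, index=[f"cluster_{j}" for j in range(k)], columns=std.columns
        ),
        fuzzifier=m,
        hard_labels=labels,
        n_iterations=iteration,
        objective_trace=trace,
    )


def cluster_membership_table(
    result: FuzzyClusteringResult, gene_subset: Sequence[str]
) -> pd.Series:
    """Per-cluster counts of a gene subset's hard assignments."""
    subset = [g for g in gene_subset if g in result.hard_labels.index]
    k = result.memberships.shape[1]
    counts = pd.Series(0, index=range(k), name="n_genes")
    for g in subset:
        counts[int(result.hard_labels[g])] += 1
    return counts
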