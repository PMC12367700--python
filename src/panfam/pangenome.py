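"""Orthogroup-by-accession occupancy / copy-number matrices and the
core / soft-core / shell / cloud conservation classification."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cluster import OrthoCluster

__all__ = [
    "OccupancyClass",
    "build_matrices",
    "classify_occupancy",
    "occupancy_thresholds",
    "category_summary",
]

LABELS = ("core", "softcore", "shell", "cloud")


@dataclass(frozen=True)
class OccupancyClass:
    orthogroup: str
    occupancy: int
    label: str


def build_matrices(
    clusters: Sequence[OrthoCluster], accessions: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the presence (0/1) and copy-number matrices.

    Rows are orthogroup ids, columns accession ids. The copy-number cell is
    the member count of the orthogroup in that accession; presence is its
    indicator. Raises when a member belongs to an unlisted accession.
    """
    accessions = list(accessions)
    known = set(accessions)
    index = [c.cluster_id for c in clusters]
    cnv = pd.DataFrame(0, index=index, columns=accessions, dtype=int)
    for cl in clusters:
        for acc, count in cl.per_accession_counts.items():
            if acc not in known:
                raise ValueError(
                    f"cluster {cl.cluster_id} has member in unknown accession {acc!r}"
                )
            cnv.loc[cl.cluster_id, acc] = count
    occ = (cnv > 0).astype(int)
    return occ, cnv


def occupancy_thresholds(n_accessions: int, strict_cloud: bool = False) -> dict[str, tuple[int, int]]:
    """Occupancy ranges (inclusive) per conservation label.

    For n accessions: core = n; soft-core = ceil(0.9 n) .. n-1; cloud =
    1 .. max(1, floor(0.1 n)); shell is the remainder. ``strict_cloud``
    restricts cloud to occupancy 1 (single accession), widening shell. For
    n = 20 the default gives the conventional 20 / 18-19 / 3-17 / 1-2
    partition.
    """
    if n_accessions < 3:
        raise ValueError("occupancy classification needs at least 3 accessions")
    n = n_accessions
    softcore_lo = math.ceil(0.9 * n)
    cloud_hi = 1 if strict_cloud else max(1, math.floor(0.1 * n))
    if softcore_lo >= n:
        softcore_lo = n  # soft-core range empty for small n
    shell_lo = cloud_hi + 1
    shell_hi = softcore_lo - 1
    return {
        "core": (n, n),
        "softcore": (softcore_lo, n - 1),
        "shell": (shell_lo, shell_hi),
        "cloud": (1, cloud_hi),
    }


def classify_occupancy(
    occupancy: pd.DataFrame, n_accessions: int | None = None, strict_cloud: bool = False
) -> list[OccupancyClass]:
    """Assign each orthogroup a conservation label from its occupancy.

    The four labels form a total partition of occupancies 1..n; occupancy 0
    (an orthogroup present nowhere) is an error.
    """
    if n_accessions is None:
        n_accessions = occupancy.shape[1]
    ranges = occupancy_thresholds(n_accessions, strict_cloud=strict_cloud)
    out: list[OccupancyClass] = []
    for og, row in occupancy.iterrows():
        occ = int((row > 0).sum())
        if occ == 0:
            raise ValueError(f"orthogroup {og} has zero occupancy")
        if occ > n_accessions:
            raise ValueError(f"orthogroup {og} occupancy {occ} exceeds {n_accessions}")
        for label in LABELS:
            lo, hi = ranges[label]
            if lo <= occ <= hi:
                out.append(OccupancyClass(str(og), occ, label))
                break
        else:
            raise ValueError(f"occupancy {occ} not covered by any class range")
    return out


def category_summary(
    classes: Sequence[OccupancyClass], cnv: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Orthogroup counts (and, with a CNV matrix, gene-entry fractions) per label."""
    counts = {label: 0 for label in LABELS}
    for c in classes:
        counts[c.label] += 1
    total = sum(counts.values())
    rows = []
    gene_totals = None
    if cnv is not None:
        by_og = cnv.sum(axis=1)
        gene_totals = {label: 0 for label in LABELS}
        for c in classes:
            gene_totals[c.label] += int(by_og.loc[c.orthogroup])
    for label in LABELS:
        row = {
            "label": label,
            "n_orthogroups": counts[label],
            "fraction": counts[label] / total if total else float("nan"),
        }
        if gene_totals is not None:
            all_genes = sum(gene_totals.values())
            row["n_genes"] = gene_totals[label]
            row["gene_fraction"] = gene_totals[label] / all_genes if all_genes else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")


def classes_to_frame(classes: Sequence[OccupancyClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"orthogroup": c.orthogroup, "occupancy": c.occupancy, "label": c.label}
            for c in classes
        ]
    ).set_index("orthogroup")
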