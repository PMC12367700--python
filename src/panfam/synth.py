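"""Seed-reproducible synthetic pan-genome bundles with recorded ground truth.

The generator emulates the inputs of a multi-accession gene-family study:
per-accession protein and CDS FASTA with controlled within- and
between-orthogroup sequence identity, GFF3 gene models on synthetic
chromosomes, TE and PAV annotation tables with planted position classes,
tissue and salt-stress time-course expression matrices with planted
temporal clusters, promoter sequences with planted transcription-factor
binding sites, a PWM file and a gene->GO map. Every planted fact is
recorded in :class:`SyntheticTruth` so each downstream stage can be
validated exactly.

Only coordinates and labels are simulated; no attempt is made to mimic
real chromosome structure or TE sequence content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .codon import GENETIC_CODE, SYNONYMOUS_FAMILIES
from .network import Pwm
from .pangenome import occupancy_thresholds
from .variation import GeneLocus, PavEvent, TEFeature

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "PangenomeBundle",
    "SyntheticConfigError",
    "generate_pangenome",
    "mutate_protein",
    "generate_cds_with_bias",
    "generate_timecourse_expression",
    "plant_motifs",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# codons per amino acid split by third-position composition
_GC_ENDING = {
    aa: tuple(c for c in fam if c[2] in "GC")
    for aa, fam in SYNONYMOUS_FAMILIES.items()
}
_AT_ENDING = {
    aa: tuple(c for c in fam if c[2] in "AT")
    for aa, fam in SYNONYMOUS_FAMILIES.items()
}


class SyntheticConfigError(ValueError):
    """Raised for impossible generator configurations."""


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic pan-genome.

    Defaults mirror the emulated study design: 20 accessions with planted
    orthogroup occupancy in the four conservation classes, ~300-codon gene
    models, high within-orthogroup protein identity, a 2 kb TE flank
    window, and a 4-point stress time course with planted expression
    clusters.
    """

    n_accessions: int = 20
    n_core: int = 30
    n_softcore: int = 10
    n_shell: int = 10
    n_cloud: int = 10
    mean_cds_len_codons: int = 300
    within_group_identity: float = 0.98
    between_group_identity: float = 0.30
    gc3_range: tuple[float, float] = (0.35, 0.90)
    n_te_per_accession: int = 30
    te_window_bp: int = 2000
    n_timepoints: int = 4
    n_planted_expression_clusters: int = 4
    n_background_genes: int = 120
    duplicate_rate: float = 0.12
    dispensable_extra_divergence: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_core, self.n_softcore, self.n_shell, self.n_cloud)
        if any(c < 0 for c in counts) or sum(counts) == 0:
            raise SyntheticConfigError("orthogroup class counts must be >= 0, sum > 0")
        if not (0.95 < self.within_group_identity <= 1.0):
            raise SyntheticConfigError("within_group_identity must be in (0.95, 1.0]")
        if not (0.0 <= self.between_group_identity <= 0.5):
            raise SyntheticConfigError("between_group_identity must be in [0, 0.5]")
        if self.between_group_identity >= self.within_group_identity:
            raise SyntheticConfigError("between-group identity must be < within-group")
        lo, hi = self.gc3_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SyntheticConfigError("gc3_range must be ordered within [0, 1]")
        if self.mean_cds_len_codons < 120:
            raise SyntheticConfigError("mean_cds_len_codons must be >= 120")
        try:
            ranges = occupancy_thresholds(self.n_accessions)
        except ValueError as exc:
            raise SyntheticConfigError(str(exc)) from None
        for label, n in zip(("core", "softcore", "shell", "cloud"), counts):
            lo_r, hi_r = ranges[label]
            if n > 0 and lo_r > hi_r:
                raise SyntheticConfigError(
                    f"{label} orthogroups requested but occupancy range is empty "
                    f"for {self.n_accessions} accessions"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated bundle."""

    occupancy_class: dict[str, str] = field(default_factory=dict)
    occupancy: dict[str, int] = field(default_factory=dict)
    members: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    copy_numbers: dict[str, dict[str, int]] = field(default_factory=dict)
    te_labels: list[tuple[TEFeature, str, str]] = field(default_factory=list)
    pav_overlaps: list[tuple[str, str, str]] = field(default_factory=list)
    expression_clusters: dict[str, int] = field(default_factory=dict)
    motif_sites: list[tuple[str, int]] = field(default_factory=list)
    regulated_targets: list[str] = field(default_factory=list)
    enriched_term: str = ""

    def gene_to_orthogroup(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for og, per_acc in self.members.items():
            for genes in per_acc.values():
                for g in genes:
                    if g in out:
                        raise ValueError(f"gene {g} appears in two orthogroups")
                    out[g] = og
        return out


@dataclass
class PangenomeBundle:
    """In-memory synthetic bundle; ``write`` lays it out as text files."""

    config: SyntheticConfig
    accessions: list[str]
    proteins: dict[str, dict[str, str]]  # accession -> gene -> protein seq
    cds: dict[str, dict[str, str]]  # accession -> gene -> CDS
    gene_models: dict[str, list[GeneLocus]]  # accession -> loci
    te_tables: dict[str, list[TEFeature]]
    pav_events: list[PavEvent]
    tissue_expression: pd.DataFrame
    timecourse_expression: pd.DataFrame
    promoters: dict[str, str]
    pwm: Pwm
    go_map: dict[str, list[str]]
    truth: SyntheticTruth

    @property
    def reference_accession(self) -> str:
        return self.accessions[0]

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for acc in self.accessions:
            pio.write_fasta(out / f"{acc}.protein.fasta", self.proteins[acc])
            pio.write_fasta(out / f"{acc}.cds.fasta", self.cds[acc])
            pio.write_gff3(out / f"{acc}.gff3", self.gene_models[acc])
            pio.write_te_table(out / f"{acc}.te.tsv", self.te_tables[acc])
        pio.write_pav_table(out / "pav.tsv", self.pav_events)
        pio.write_expression(out / "tissue_expression.tsv", self.tissue_expression)
        pio.write_expression(out / "timecourse_expression.tsv", self.timecourse_expression)
        pio.write_fasta(out / "promoters.fasta", self.promoters)
        pio.write_pwm_meme(out / "motif.meme", self.pwm)
        pio.write_go_map(out / "gene2go.tsv", self.go_map)
        self._write_truth(out / "truth")
        return out

    def _write_truth(self, truth_dir: Path) -> None:
        truth_dir.mkdir(exist_ok=True)
        t = self.truth
        pd.DataFrame(
            [
                {"orthogroup": og, "label": t.occupancy_class[og], "occupancy": t.occupancy[og]}
                for og in sorted(t.occupancy_class)
            ]
        ).to_csv(truth_dir / "occupancy.tsv", sep="\t", index=False)
        rows = []
        for og in sorted(t.members):
            for acc in sorted(t.members[og]):
                for g in t.members[og][acc]:
                    rows.append({"orthogroup": og, "accession_id": acc, "gene_id": g})
        pd.DataFrame(rows, columns=["orthogroup", "accession_id", "gene_id"]).to_csv(
            truth_dir / "members.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"chrom": te.chrom, "start": te.start, "end": te.end, "code": te.code,
                 "gene_id": gene, "position": label}
                for te, gene, label in t.te_labels
            ],
            columns=["chrom", "start", "end", "code", "gene_id", "position"],
        ).to_csv(truth_dir / "te_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": g, "accession_id": a, "state": s} for g, a, s in t.pav_overlaps],
            columns=["gene_id", "accession_id", "state"],
        ).to_csv(truth_dir / "pav_overlaps.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(t.expression_clusters.items()), columns=["gene_id", "cluster"]
        ).to_csv(truth_dir / "expression_clusters.tsv", sep="\t", index=False)
        pd.DataFrame(
            t.motif_sites, columns=["promoter_id", "offset"]
        ).to_csv(truth_dir / "motif_sites.tsv", sep="\t", index=False)


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Substitute residues to reach a target identity to the input.

    Exactly round((1 - target) * len) positions are replaced with a
    different random residue, so the realized identity is within one
    position of the target.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not (0.0 <= target_identity <= 1.0):
        raise ValueError("target_identity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(seq)
    k = int(round((1.0 - target_identity) * n))
    if k == 0:
        return seq
    positions = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [aa for aa in _AA20 if aa != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, size=length))


def _codon_for(aa: str, gc3: float, rng: np.random.Generator) -> str:
    gc_opts = _GC_ENDING[aa]
    at_opts = _AT_ENDING[aa]
    if gc_opts and (not at_opts or rng.random() < gc3):
        return gc_opts[rng.integers(len(gc_opts))]
    return at_opts[rng.integers(len(at_opts))]


def generate_cds_with_bias(n_codons: int, gc3: float, seed: int) -> str:
    """Random CDS (ATG ... stop) whose synonymous third positions hit a
    target GC3 fraction.

    ``n_codons`` counts all codons including start and stop. Amino acids
    are drawn uniformly; within each family a G/C-ending codon is chosen
    with probability ``gc3``, so the realized GC3s converges to the target.
    """
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2")
    if not (0.0 <= gc3 <= 1.0):
        raise ValueError("gc3 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    internal = []
    for _ in range(n_codons - 2):
        aa = _AA20[rng.integers(20)]
        internal.append(_codon_for(aa, gc3, rng))
    stop = _STOPS[rng.integers(3)]
    return "ATG" + "".join(internal) + stop


def _protein_to_cds(protein: str, gc3: float, rng: np.random.Generator) -> str:
    body = "".join(_codon_for(aa, gc3, rng) for aa in protein)
    return body + _STOPS[rng.integers(3)]


def _mutate_cds(
    cds: str,
    protein_identity: float,
    synonymous_rate: float,
    gc3: float,
    rng: np.random.Generator,
) -> str:
    """Codon-level divergence: nonsynonymous codon swaps to hit a protein
    identity target plus synonymous swaps at ``synonymous_rate``."""
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
    stop = cds[-3:]
    n = len(codons)
    k_nonsyn = int(round((1.0 - protein_identity) * n))
    mutable = np.arange(1, n)  # keep the start codon
    nonsyn_pos = rng.choice(mutable, size=min(k_nonsyn, len(mutable)), replace=False)
    nonsyn_set = set(int(p) for p in nonsyn_pos)
    for pos in nonsyn_set:
        old_aa = GENETIC_CODE[codons[pos]]
        new_aa = old_aa
        while new_aa == old_aa:
            new_aa = _AA20[rng.integers(20)]
        codons[pos] = _codon_for(new_aa, gc3, rng)
    for pos in range(1, n):
        if pos in nonsyn_set:
            continue
        if rng.random() < synonymous_rate:
            aa = GENETIC_CODE[codons[pos]]
            fam = SYNONYMOUS_FAMILIES[aa]
            if len(fam) > 1:
                codons[pos] = _codon_for(aa, gc3, rng)
    return "".join(codons) + stop


_TE_CODES = ("DTC", "DTM", "DTH", "DHH", "RLC", "RLG", "RIX")
_TE_CODE_WEIGHTS = (0.30, 0.25, 0.18, 0.12, 0.07, 0.05, 0.03)
_TISSUES = ("caryopsis", "coleoptile", "inflorescence", "root", "shoot")


def generate_timecourse_expression(
    n_genes: int,
    n_clusters: int,
    noise_sd: float,
    seed: int,
    n_timepoints: int = 4,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Time-course FPKM matrix with planted temporal clusters.

    Each cluster has a distinct prototype shape (monotone up/down, early or
    late peak, transient dip, ...); a gene's profile is its cluster
    prototype plus N(0, noise_sd) shape noise, mapped onto an FPKM scale
    with a random per-gene amplitude. Returns the matrix and the true
    labels.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_genes < n_clusters:
        raise ValueError("n_genes must be >= n_clusters")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_timepoints)
    shapes = [
        t,  # monotone up
        1.0 - t,  # monotone down
        np.exp(-(((t - 0.25) / 0.2) ** 2)),  # early peak
        np.exp(-(((t - 0.8) / 0.2) ** 2)),  # late peak
        1.0 - np.exp(-(((t - 0.5) / 0.2) ** 2)),  # transient dip
        np.cos(2 * np.pi * t),  # down-up
    ]
    prototypes = []
    for j in range(n_clusters):
        base = shapes[j % len(shapes)]
        if j >= len(shapes):  # phase-shifted variants beyond the base set
            base = np.roll(base, j // len(shapes))
        z = (base - base.mean()) / (base.std() if base.std() > 0 else 1.0)
        prototypes.append(z)
    labels = np.arange(n_genes) % n_clusters  # cyclic: clusters mix gene kinds
    rows = np.empty((n_genes, n_timepoints))
    for i in range(n_genes):
        shape = prototypes[labels[i]] + rng.normal(0.0, noise_sd, size=n_timepoints)
        amplitude = rng.uniform(15.0, 40.0)
        baseline = rng.uniform(40.0, 80.0)
        rows[i] = np.maximum(baseline + amplitude * shape, 0.0)
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    columns = [f"t{j}" for j in range(n_timepoints)]
    df = pd.DataFrame(rows, index=list(gene_ids), columns=columns)
    return df, pd.Series(labels, index=list(gene_ids), name="cluster")


def plant_motifs(
    promoters: Mapping[str, str],
    pwm: Pwm,
    n_sites: int,
    seed: int,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Plant the PWM consensus word into promoters at random offsets.

    At most one site per promoter; an error is raised when ``n_sites``
    exceeds the number of promoters long enough to carry the motif.
    Returns the modified promoters and the (promoter_id, offset) list.
    """
    w = pwm.width
    eligible = [pid for pid, seq in promoters.items() if len(seq) >= w]
    if n_sites > len(eligible):
        raise ValueError(
            f"cannot plant {n_sites} sites into {len(eligible)} eligible promoters"
        )
    rng = np.random.default_rng(seed)
    word = pwm.consensus
    out = dict(promoters)
    chosen = sorted(rng.choice(len(eligible), size=n_sites, replace=False))
    sites: list[tuple[str, int]] = []
    for idx in chosen:
        pid = eligible[idx]
        seq = out[pid]
        offset = int(rng.integers(0, len(seq) - w + 1))
        out[pid] = seq[:offset] + word + seq[offset + w :]
        sites.append((pid, offset))
    return out, sites


def _nac_like_pwm() -> Pwm:
    """A strongly informative 10-bp binding-site count matrix."""
    consensus = "TTGCGTGTCA"
    w = len(consensus)
    counts = np.full((4, w), 2.0)
    order = "ACGT"
    for j, base in enumerate(consensus):
        counts[order.index(base), j] = 44.0
    return Pwm(motif_id="NACBS_syn", counts=counts)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def generate_pangenome(config: SyntheticConfig) -> PangenomeBundle:
    """Generate the full synthetic bundle for a configuration.

    A single seed sequence drives everything through spawned substreams
    (one per generation stage and accession), so the bundle is
    byte-reproducible and adding accessions does not perturb earlier ones.
    """
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    keys = [
        "ancestors", "occupancy", "members", "layout", "te", "pav",
        "tissue", "timecourse", "promoters", "go",
    ]
    streams = {k: np.random.default_rng(ss) for k, ss in zip(keys, root_ss.spawn(len(keys)))}
    accessions = [f"acc{i + 1:02d}" for i in range(config.n_accessions)]
    truth = SyntheticTruth()
    ranges = occupancy_thresholds(config.n_accessions)

    # --- orthogroup ancestors -------------------------------------------------
    rng = streams["ancestors"]
    class_counts = [
        ("core", config.n_core),
        ("softcore", config.n_softcore),
        ("shell", config.n_shell),
        ("cloud", config.n_cloud),
    ]
    n_ogg = sum(n for _, n in class_counts)
    scaffold = _random_protein(config.mean_cds_len_codons - 2, rng)
    gc3_lo, gc3_hi = config.gc3_range
    ogg_ids: list[str] = []
    ogg_class: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    ogg_gc3: dict[str, float] = {}
    i_ogg = 0
    for label, count in class_counts:
        for _ in range(count):
            og = f"tOG{i_ogg + 1:04d}"
            i_ogg += 1
            ogg_ids.append(og)
            ogg_class[og] = label
            length_jitter = int(rng.integers(-20, 21))
            length = max(110, config.mean_cds_len_codons - 2 + length_jitter)
            anc = mutate_protein(
                scaffold, config.between_group_identity, int(rng.integers(2**31))
            )
            if length <= len(anc):
                anc = anc[:length]
            else:
                anc = anc + _random_protein(length - len(anc), rng)
            ancestors[og] = anc
            # codon-bias gradient across orthogroups
            ogg_gc3[og] = gc3_lo + (gc3_hi - gc3_lo) * (len(ogg_ids) - 1) / max(1, n_ogg - 1)

    # --- occupancy and member assignment -------------------------------------
    rng = streams["occupancy"]
    member_accs: dict[str, list[str]] = {}
    for og in ogg_ids:
        lo, hi = ranges[ogg_class[og]]
        occ = int(rng.integers(lo, hi + 1))
        carriers = sorted(rng.choice(config.n_accessions, size=occ, replace=False))
        member_accs[og] = [accessions[i] for i in carriers]
        truth.occupancy[og] = occ
        truth.occupancy_class[og] = ogg_class[og]

    rng = streams["members"]
    proteins: dict[str, dict[str, str]] = {acc: {} for acc in accessions}
    cds: dict[str, dict[str, str]] = {acc: {} for acc in accessions}
    for og in ogg_ids:
        anc_protein = ancestors[og]
        gc3 = ogg_gc3[og]
        anc_cds = _protein_to_cds(anc_protein, gc3, rng)
        identity = config.within_group_identity
        if ogg_class[og] != "core":
            identity = max(0.96, identity - config.dispensable_extra_divergence)
        # members diverge from the common ancestor at half the target
        # divergence, so member-to-member (and member-to-representative)
        # identity realizes the configured within-group value
        identity = 1.0 - (1.0 - identity) / 2.0
        syn_rate = 0.03 if ogg_class[og] == "core" else 0.06
        truth.members[og] = {}
        truth.copy_numbers[og] = {}
        for acc in member_accs[og]:
            n_copies = 1
            if rng.random() < config.duplicate_rate:
                n_copies = 2
            genes = []
            for copy in range(n_copies):
                gene_id = f"{acc}_{og}_{copy + 1}"
                member_cds = _mutate_cds(
                    "ATG" + anc_cds, identity, synonymous_rate=syn_rate, gc3=gc3, rng=rng
                )
                member_protein = "".join(
                    GENETIC_CODE[member_cds[i : i + 3]]
                    for i in range(0, len(member_cds) - 3, 3)
                )
                proteins[acc][gene_id] = member_protein
                cds[acc][gene_id] = member_cds
                genes.append(gene_id)
            truth.members[og][acc] = genes
            truth.copy_numbers[og][acc] = n_copies

    # --- gene models ----------------------------------------------------------
    # copies of one orthogroup sit adjacently (tandem-like); orthogroups are
    # split over two synthetic chromosomes
    rng = streams["layout"]
    gene_models: dict[str, list[GeneLocus]] = {}
    for acc in accessions:
        loci = []
        pos = {"chr1": 10_000, "chr2": 10_000}
        for og_index, og in enumerate(ogg_ids):
            chrom = "chr1" if og_index < n_ogg // 2 else "chr2"
            for gene_id in truth.members.get(og, {}).get(acc, []):
                length = len(cds[acc][gene_id])
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(GeneLocus(gene_id, chrom, pos[chrom], pos[chrom] + length, strand))
                pos[chrom] += length + 9_000
        gene_models[acc] = loci

    # --- TEs with planted position labels ------------------------------------
    rng = streams["te"]
    te_tables: dict[str, list[TEFeature]] = {}
    code_p = np.asarray(_TE_CODE_WEIGHTS)
    for acc in accessions:
        tes: list[TEFeature] = []
        loci = gene_models[acc]
        if not loci:
            te_tables[acc] = tes
            continue
        for _ in range(config.n_te_per_accession):
            gene = loci[int(rng.integers(len(loci)))]
            label = ("upstream", "genic", "downstream")[int(rng.integers(3))]
            te_len = int(rng.integers(150, 900))
            win = config.te_window_bp
            if label == "genic":
                start = gene.start + int(
                    rng.integers(0, max(1, gene.end - gene.start - 50))
                )
            else:
                # strand-aware flank: upstream is 5' of the gene
                margin = win - te_len
                off = int(rng.integers(50, max(51, margin))) if margin > 51 else 1
                left = (label == "upstream") == (gene.strand == "+")
                if left:
                    start = max(0, gene.start - off - te_len)
                else:
                    start = gene.end + off
            code = _TE_CODES[int(rng.choice(len(_TE_CODES), p=code_p))]
            te = TEFeature(gene.chrom, start, start + te_len, "+", code)
            tes.append(te)
            if acc == accessions[0]:
                truth.te_labels.append((te, gene.gene_id, label))
        te_tables[acc] = tes

    # --- PAV events (deletions relative to the reference accession) ----------
    rng = streams["pav"]
    pav_events: list[PavEvent] = []
    ref = accessions[0]
    ref_loci = {g.gene_id: g for g in gene_models[ref]}
    for og in ogg_ids:
        carriers = set(member_accs[og])
        if ref not in carriers:
            continue
        ref_genes = truth.members[og][ref]
        absent = [a for a in accessions[1:] if a not in carriers]
        for acc in absent:
            gene = ref_loci[ref_genes[0]]
            pad = int(rng.integers(0, 500))
            pav = PavEvent(acc, gene.chrom, max(0, gene.start - pad), gene.end + pad, "deletion")
            pav_events.append(pav)
            truth.pav_overlaps.append((gene.gene_id, acc, "deletion"))
    # a few insertions that do not overlap reference genes (inter-genic)
    for _ in range(max(2, len(ogg_ids) // 10)):
        acc = accessions[1 + int(rng.integers(config.n_accessions - 1))]
        pos = 1_000 + int(rng.integers(2_000))
        pav_events.append(PavEvent(acc, "chr1", pos, pos + int(rng.integers(50, 800)), "insertion"))

    # --- tissue expression (reference-accession genes) ------------------------
    rng = streams["tissue"]
    ref_gene_ids = [g.gene_id for g in gene_models[ref]]
    tissue = pd.DataFrame(
        np.round(rng.gamma(2.0, 15.0, size=(len(ref_gene_ids), len(_TISSUES))), 4),
        index=ref_gene_ids,
        columns=list(_TISSUES),
    )

    # --- time-course expression with planted clusters -------------------------
    # three replicate libraries per time point, as in a typical stress
    # RNA-seq design; clustering averages replicates, correlations use all
    # columns
    n_family = len(ref_gene_ids)
    n_genes = n_family + config.n_background_genes
    bg_ids = [f"bg{i + 1:05d}" for i in range(config.n_background_genes)]
    tc_ids = ref_gene_ids + bg_ids
    rng = streams["timecourse"]
    mean_profile, labels = generate_timecourse_expression(
        n_genes,
        config.n_planted_expression_clusters,
        noise_sd=0.05,
        seed=int(rng.integers(2**31)),
        n_timepoints=config.n_timepoints,
        gene_ids=tc_ids,
    )
    n_reps = 3
    rep_cols = []
    rep_data = []
    for j in range(config.n_timepoints):
        for r in range(n_reps):
            rep_cols.append(f"t{j}_r{r + 1}")
            rep_data.append(
                np.maximum(
                    mean_profile.iloc[:, j].to_numpy()
                    + rng.normal(0.0, 2.0, size=n_genes),
                    0.0,
                )
            )
    timecourse = pd.DataFrame(
        np.column_stack(rep_data), index=tc_ids, columns=rep_cols
    )
    # plant a handful of low-expression genes to exercise the FPKM filter
    n_low = max(2, n_genes // 20)
    low_idx = rng.choice(n_genes, size=n_low, replace=False)
    scale = pd.Series(1.0, index=timecourse.index)
    scale.iloc[low_idx] = 0.05
    timecourse = timecourse.mul(scale, axis=0).round(4)
    for g in timecourse.index[low_idx]:
        labels = labels.drop(g)
    truth.expression_clusters = {g: int(c) for g, c in labels.items()}

    # --- promoters, PWM, planted motif sites ----------------------------------
    rng = streams["promoters"]
    pwm = _nac_like_pwm()
    promoters = {g: _random_dna(2000, rng) for g in bg_ids}
    # regulated targets: background genes sharing the focal genes' cluster
    focal_cluster = int(labels.get(ref_gene_ids[0], 0)) if len(ref_gene_ids) else 0
    candidates = [
        g
        for g in bg_ids
        if truth.expression_clusters.get(g) == focal_cluster
    ]
    n_targets = max(1, len(candidates) // 2) if candidates else 0
    targets = (
        sorted(str(g) for g in rng.choice(candidates, size=n_targets, replace=False))
        if n_targets
        else []
    )
    sites: list[tuple[str, int]] = []
    for g in targets:
        offset = int(rng.integers(0, 2000 - pwm.width + 1))
        seq = promoters[g]
        promoters[g] = seq[:offset] + pwm.consensus + seq[offset + pwm.width :]
        sites.append((g, offset))
    truth.motif_sites = sites
    truth.regulated_targets = targets

    # --- GO map with one planted enriched term --------------------------------
    rng = streams["go"]
    terms = [f"GO:{7000 + i:07d}" for i in range(8)]
    enriched = "GO:0009651"  # salt-stress-response-like planted term
    go_map: dict[str, list[str]] = {}
    for g in tc_ids:
        k = int(rng.integers(1, 3))
        assigned = sorted(str(t) for t in rng.choice(terms, size=k, replace=False))
        go_map[g] = assigned
    for g in targets:
        if rng.random() < 0.8:
            go_map[g] = sorted(set(go_map[g]) | {enriched})
    truth.enriched_term = enriched

    return PangenomeBundle(
        config=config,
        accessions=accessions,
        proteins=proteins,
        cds=cds,
        gene_models=gene_models,
        te_tables=te_tables,
        pav_events=pav_events,
        tissue_expression=tissue,
        timecourse_expression=timecourse,
        promoters=promoters,
        pwm=pwm,
        go_map=go_map,
        truth=truth,
    )
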