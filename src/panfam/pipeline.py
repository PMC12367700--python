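"""End-to-end driver chaining all analysis stages on a bundle directory.

The pipeline consumes a bundle laid out as the synthetic generator writes
it (per-accession protein/CDS FASTA, GFF3, TE tables, a PAV table,
expression matrices, a PWM and a GO map) and produces a report directory
of stage TSVs, basic plots and a summary. Identical configuration and
seed give a byte-identical report: nothing in the outputs depends on wall
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "panfam"  # deterministic SVG element ids
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as pio
from .cluster import OrthoCluster, greedy_cluster
from .codon import (
    codon_profile,
    count_codons,
    enc_expected,
    optimal_codons,
    profiles_to_frame,
    rscu,
)
from .expression import (
    cluster_membership_table,
    filter_and_standardize,
    fuzzy_cmeans,
    tissue_summary,
)
from .network import assemble_network, enrich, pearson_edges, pwm_scan
from .pangenome import (
    build_matrices,
    category_summary,
    classes_to_frame,
    classify_occupancy,
)
from .selection import codon_align, kaks_group_compare, ng86
from .synth import SyntheticConfig, generate_pangenome
from .variation import classify_te_position, classify_duplication, pav_gene_overlap, tally_te_classes

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("cluster", "matrix", "variation", "selection", "codon", "expression", "network")

_STAGE_DEPS = {
    "matrix": ("cluster",),
    "variation": ("cluster",),
    "selection": ("cluster", "matrix"),
    "network": ("expression",),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str | Path = "panfam_report"
    input_dir: str | Path | None = None  # None -> generate a synthetic bundle
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # clustering
    min_identity: float = 0.95
    min_longer_cov: float = 0.90
    min_aln_len: int = 100
    prefilter: bool = True
    # occupancy
    strict_cloud: bool = False
    # variation
    te_window_bp: int = 2000
    proximal_max_intervening: int = 10
    # expression / clustering
    min_mean_fpkm: float = 10.0
    fcm_clusters: int = 10
    fcm_fuzzifier: float = 1.25
    # network
    r_min: float = 0.9
    p_max: float = 0.01
    motif_p_max: float = 1e-4
    make_plots: bool = True


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def _average_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns named '<condition>_r<k>'; pass through
    matrices without replicate suffixes."""
    if not all("_r" in c for c in expr.columns):
        return expr
    groups = [c.rsplit("_r", 1)[0] for c in expr.columns]
    out = expr.T.groupby(groups, sort=False).mean().T
    return out


def _save_fig(fig, path: Path) -> None:
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in dependency order; returns the report dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        missing = [d for d in _STAGE_DEPS.get(stage, ()) if d not in enabled]
        if missing:
            raise StageError(stage, RuntimeError(f"requires disabled stage(s) {missing}"))

    if config.input_dir is None:
        syn = config.synthetic
        syn.seed = config.seed
        bundle_dir = out / "bundle"
        generate_pangenome(syn).write(bundle_dir)
        _log(log, f"synthetic bundle written to {bundle_dir.name}")
    else:
        bundle_dir = Path(config.input_dir)

    accessions = sorted(p.name.split(".")[0] for p in bundle_dir.glob("*.protein.fasta"))
    if not accessions:
        raise StageError("input", RuntimeError(f"no *.protein.fasta in {bundle_dir}"))
    reference = accessions[0]
    _log(log, f"{len(accessions)} accessions; reference {reference}")

    records = []
    cds_by_gene: dict[str, str] = {}
    for acc in accessions:
        recs = pio.read_protein_records(bundle_dir / f"{acc}.protein.fasta", acc)
        records.extend(recs)
        cds_by_gene.update(pio.read_fasta(bundle_dir / f"{acc}.cds.fasta"))
    _log(log, f"loaded {len(records)} proteins, {len(cds_by_gene)} CDS")

    summary: dict[str, object] = {"n_accessions": len(accessions), "n_genes": len(records)}
    clusters: list[OrthoCluster] = []
    classes = None
    occ = cnv = None
    fcm_result = None
    std = None

    for stage in enabled:
        try:
            if stage == "cluster":
                clusters = greedy_cluster(
                    records,
                    min_identity=config.min_identity,
                    min_longer_cov=config.min_longer_cov,
                    min_aln_len=config.min_aln_len,
                    prefilter=config.prefilter,
                )
                rows = [
                    {
                        "cluster_id": c.cluster_id,
                        "representative": c.representative,
                        "gene_id": g,
                        "accession_id": a,
                    }
                    for c in clusters
                    for g, a in zip(c.members, c.member_accessions)
                ]
                pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
                summary["n_orthogroups"] = len(clusters)
                _log(log, f"cluster: {len(records)} proteins -> {len(clusters)} orthogroups")

            elif stage == "matrix":
                occ, cnv = build_matrices(clusters, accessions)
                classes = classify_occupancy(occ, strict_cloud=config.strict_cloud)
                occ.to_csv(out / "occupancy_matrix.tsv", sep="\t", index_label="orthogroup")
                cnv.to_csv(out / "cnv_matrix.tsv", sep="\t", index_label="orthogroup")
                classes_to_frame(classes).to_csv(out / "occupancy_classes.tsv", sep="\t")
                cat = category_summary(classes, cnv)
                cat.to_csv(out / "category_summary.tsv", sep="\t", float_format="%.6g")
                summary["occupancy_counts"] = cat["n_orthogroups"].to_dict()
                _log(log, "matrix: class counts " + str(cat["n_orthogroups"].to_dict()))

            elif stage == "variation":
                genes = pio.read_gff3(bundle_dir / f"{reference}.gff3")
                tes = pio.read_te_table(bundle_dir / f"{reference}.te.tsv")
                by_chrom: dict[str, list] = {}
                for g in genes:
                    by_chrom.setdefault(g.chrom, []).append(g)
                assignments = []
                assign_rows = []
                for te in tes:
                    best = "none"
                    best_gene = ""
                    for g in by_chrom.get(te.chrom, ()):
                        label = classify_te_position(te, g, window_bp=config.te_window_bp)
                        if label != "none":
                            best, best_gene = label, g.gene_id
                            break
                    assignments.append((te, best))
                    assign_rows.append(
                        {"chrom": te.chrom, "start": te.start, "end": te.end,
                         "code": te.code, "gene_id": best_gene, "position": best}
                    )
                pd.DataFrame(assign_rows).to_csv(out / "te_positions.tsv", sep="\t", index=False)
                tallies = tally_te_classes(assignments)
                pd.DataFrame(
                    [(k, c, n) for k, counter in tallies.items() for c, n in sorted(counter.items())],
                    columns=["tally", "category", "count"],
                ).to_csv(out / "te_tallies.tsv", sep="\t", index=False)
                pavs = pio.read_pav_table(bundle_dir / "pav.tsv")
                overlaps = pav_gene_overlap(pavs, genes)
                overlaps.to_csv(out / "pav_gene_overlaps.tsv", sep="\t", index=False)
                ref_gene_ids = {g.gene_id for g in genes}
                pairs = []
                for c in clusters:
                    ref_members = [g for g in c.members if g in ref_gene_ids]
                    pairs.extend(
                        (a, b)
                        for i, a in enumerate(ref_members)
                        for b in ref_members[i + 1 :]
                    )
                dup = classify_duplication(
                    genes, pairs, proximal_max_intervening=config.proximal_max_intervening
                )
                pd.DataFrame(
                    sorted(dup.items()), columns=["gene_id", "duplication_type"]
                ).to_csv(out / "duplication_types.tsv", sep="\t", index=False)
                dup_counts = pd.Series(dup).value_counts().to_dict()
                summary["te_positions"] = dict(sorted(tallies["position"].items()))
                summary["n_pav_overlaps"] = int(len(overlaps))
                summary["duplication_counts"] = dup_counts
                _log(log, f"variation: {len(tes)} TEs, {len(overlaps)} PAV overlaps, "
                          f"duplication {dup_counts}")

            elif stage == "selection":
                per_og = {}
                rows = []
                for c in clusters:
                    if len(c.members) < 2:
                        continue
                    rep_cds = cds_by_gene[c.representative]
                    vals = []
                    for g in c.members:
                        if g == c.representative:
                            continue
                        a, b = codon_align(rep_cds, cds_by_gene[g])
                        res = ng86(a, b)
                        vals.append(res)
                        rows.append(
                            {"orthogroup": c.cluster_id, "pair": f"{c.representative}|{g}",
                             "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                             "Ka": res.Ka, "Ks": res.Ks, "ratio": res.ratio}
                        )
                    ka = [v.Ka for v in vals if not math.isnan(v.Ka)]
                    ks = [v.Ks for v in vals if not math.isnan(v.Ks)]
                    ratios = [v.ratio for v in vals if not math.isnan(v.ratio)]
                    if ka and ks:
                        from .selection import KaKsResult

                        per_og[c.cluster_id] = KaKsResult(
                            S=float("nan"), N=float("nan"), Sd=float("nan"), Nd=float("nan"),
                            ps=float("nan"), pn=float("nan"),
                            Ka=float(np.mean(ka)), Ks=float(np.mean(ks)),
                            ratio=float(np.mean(ratios)) if ratios else float("nan"),
                        )
                pd.DataFrame(rows).to_csv(
                    out / "kaks_pairs.tsv", sep="\t", index=False, float_format="%.6g"
                )
                summary["n_kaks_orthogroups"] = len(per_og)
                if classes is not None and per_og:
                    label_map = {c.orthogroup: c.label for c in classes}
                    try:
                        tests = kaks_group_compare(per_og, label_map)
                        pd.DataFrame(tests).T.to_csv(
                            out / "kaks_core_vs_dispensable.tsv", sep="\t",
                            float_format="%.6g", index_label="metric",
                        )
                        summary["kaks_tests"] = {k: v["p"] for k, v in tests.items()}
                        _log(log, "selection: core-vs-dispensable p " +
                                  str({k: round(v["p"], 5) for k, v in tests.items()}))
                    except ValueError as exc:
                        _log(log, f"selection: group contrast skipped ({exc})")

            elif stage == "codon":
                ref_cds = pio.read_fasta(bundle_dir / f"{reference}.cds.fasta")
                counts = [count_codons(s, gene_id=g) for g, s in ref_cds.items()]
                enc_by_gene = {}
                profs = []
                for c in counts:
                    p = codon_profile(c)
                    profs.append(p)
                    enc_by_gene[c.gene_id] = p.enc
                # CAI reference: lowest-ENC decile as the high-expression proxy
                defined = [c for c in counts if not math.isnan(enc_by_gene[c.gene_id])]
                defined.sort(key=lambda c: (enc_by_gene[c.gene_id], c.gene_id))
                n_ref = max(1, len(defined) // 10)
                reference_set = defined[:n_ref]
                profs = [codon_profile(c, reference=reference_set) for c in counts]
                frame = profiles_to_frame(profs)
                frame.to_csv(out / "codon_profiles.tsv", sep="\t", float_format="%.6g")
                rscu_matrix = pd.DataFrame(
                    {c.gene_id: rscu(c) for c in counts}
                ).T.sort_index(axis=1)
                rscu_matrix.to_csv(
                    out / "rscu_matrix.tsv", sep="\t", float_format="%.6g",
                    index_label="gene_id",
                )
                try:
                    opt = optimal_codons(counts)
                    opt.to_csv(out / "optimal_codons.tsv", sep="\t", float_format="%.6g")
                    summary["optimal_codons"] = sorted(opt.index[opt["is_optimal"]])
                except ValueError as exc:
                    _log(log, f"codon: optimal-codon step skipped ({exc})")
                summary["enc_mean"] = float(frame["enc"].mean())
                summary["cai_mean"] = float(frame["cai"].mean())
                _log(log, f"codon: {len(counts)} genes, mean ENC "
                          f"{summary['enc_mean']:.2f}, mean CAI {summary['cai_mean']:.3f}")
                if config.make_plots:
                    fig, ax = plt.subplots(figsize=(5, 4))
                    ax.scatter(frame["gc3s"], frame["enc"], s=8, alpha=0.6)
                    s = np.linspace(0.01, 0.99, 200)
                    ax.plot(s, [enc_expected(x) for x in s], "r-", lw=1)
                    ax.set_xlabel("GC3s")
                    ax.set_ylabel("ENC")
                    _save_fig(fig, out / "enc_plot.svg")
                    fig, ax = plt.subplots(figsize=(4.5, 4.5))
                    ax.scatter(frame["pr2_x"], frame["pr2_y"], s=8, alpha=0.6)
                    ax.axhline(0.5, color="r", lw=0.8)
                    ax.axvline(0.5, color="r", lw=0.8)
                    ax.set_xlabel("G3/(G3+C3)")
                    ax.set_ylabel("A3/(A3+T3)")
                    _save_fig(fig, out / "pr2_plot.svg")

            elif stage == "expression":
                tissues = pio.read_expression(bundle_dir / "tissue_expression.tsv")
                group_map = None
                if clusters:
                    gene_to_og = {g: c.cluster_id for c in clusters for g in c.members}
                    group_map = {g: gene_to_og[g] for g in tissues.index if g in gene_to_og}
                normalized, group_means = tissue_summary(tissues, group_map)
                normalized.to_csv(
                    out / "tissue_minmax.tsv", sep="\t", float_format="%.6g",
                    index_label="gene_id",
                )
                if group_means is not None:
                    group_means.to_csv(
                        out / "tissue_group_means.tsv", sep="\t", float_format="%.6g",
                        index_label="group",
                    )
                tc = pio.read_expression(bundle_dir / "timecourse_expression.tsv")
                averaged = _average_replicates(tc)
                std = filter_and_standardize(averaged, min_mean=config.min_mean_fpkm)
                k = min(config.fcm_clusters, std.shape[0])
                fcm_result = fuzzy_cmeans(
                    std, k=k, m=config.fcm_fuzzifier, seed=config.seed
                )
                fcm_result.memberships.to_csv(
                    out / "fcm_memberships.tsv", sep="\t", float_format="%.6g",
                    index_label="gene_id",
                )
                fcm_result.hard_labels.to_frame().to_csv(out / "fcm_labels.tsv", sep="\t")
                fcm_result.centers.to_csv(
                    out / "fcm_centers.tsv", sep="\t", float_format="%.6g",
                    index_label="cluster",
                )
                family_genes = [g for g in std.index if g in cds_by_gene]
                fam_counts = cluster_membership_table(fcm_result, family_genes)
                fam_counts.to_frame().to_csv(
                    out / "fcm_family_counts.tsv", sep="\t", index_label="cluster"
                )
                summary["n_expressed_genes"] = int(std.shape[0])
                summary["fcm_sizes"] = fcm_result.hard_labels.value_counts().sort_index().to_dict()
                _log(log, f"expression: {tc.shape[0]} genes -> {std.shape[0]} after "
                          f"FPKM filter; {k} fuzzy clusters")
                if config.make_plots:
                    fig, ax = plt.subplots(figsize=(5, 4))
                    for name, row in fcm_result.centers.iterrows():
                        ax.plot(row.values, label=str(name), lw=1)
                    ax.set_xlabel("time point")
                    ax.set_ylabel("standardized expression")
                    ax.legend(fontsize=6)
                    _save_fig(fig, out / "fcm_centers.svg")

            elif stage == "network":
                tc = pio.read_expression(bundle_dir / "timecourse_expression.tsv")
                expressed = set(std.index)
                # focal genes are the family members (present in the CDS
                # catalog); candidate targets are the remaining expressed genes
                focal = [g for g in tc.index if g in cds_by_gene and g in expressed]
                edges = pearson_edges(
                    tc.loc[sorted(expressed)], focal,
                    r_min=config.r_min, p_max=config.p_max,
                )
                promoters = pio.read_fasta(bundle_dir / "promoters.fasta")
                pwm = pio.read_pwm(bundle_dir / "motif.meme")
                edge_targets = sorted({e.target for e in edges})
                hits = pwm_scan(
                    {g: promoters[g] for g in edge_targets if g in promoters},
                    pwm, p_max=config.motif_p_max,
                )
                labels_map = (
                    {g: int(v) for g, v in fcm_result.hard_labels.items()}
                    if fcm_result is not None else None
                )
                nodes, edge_df, per_cluster = assemble_network(edges, hits, labels_map)
                nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
                edge_df.to_csv(
                    out / "network_edges.tsv", sep="\t", index=False, float_format="%.6g"
                )
                go_map = pio.read_go_map(bundle_dir / "gene2go.tsv")
                retained = sorted(set(edge_df["target"])) if len(edge_df) else []
                if retained:
                    enr = enrich(retained, sorted(expressed), go_map)
                    enr.to_csv(
                        out / "go_enrichment.tsv", sep="\t", index=False,
                        float_format="%.6g",
                    )
                summary["n_edges"] = len(edges)
                summary["n_motif_hits"] = len(hits)
                summary["n_network_targets"] = len(retained)
                _log(log, f"network: {len(edges)} edges, {len(hits)} motif hits, "
                          f"{len(retained)} retained targets")
        except StageError:
            raise
        except Exception as exc:  # keep partial outputs, name the stage
            (out / "run.log").write_text("\n".join(log) + "\n")
            raise StageError(stage, exc) from exc

    with open(out / "summary.txt", "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
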