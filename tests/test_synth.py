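"""Generator correctness: determinism, planted truth, realized parameters."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from panfam.codon import GENETIC_CODE, STOP_CODONS, count_codons, third_position_composition
from panfam.network import Pwm
from panfam.synth import (
    SyntheticConfig,
    SyntheticConfigError,
    generate_cds_with_bias,
    generate_pangenome,
    generate_timecourse_expression,
    mutate_protein,
    plant_motifs,
)


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_gives_byte_identical_bundles(tmp_path):
    config = SyntheticConfig(n_accessions=4, n_core=5, n_softcore=0, n_shell=4,
                             n_cloud=3, n_background_genes=20, seed=7)
    generate_pangenome(config).write(tmp_path / "a")
    generate_pangenome(config).write(tmp_path / "b")
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")


def test_different_seed_changes_bundle(tmp_path):
    base = dict(n_accessions=4, n_core=5, n_softcore=0, n_shell=4, n_cloud=3,
                n_background_genes=20)
    generate_pangenome(SyntheticConfig(seed=1, **base)).write(tmp_path / "a")
    generate_pangenome(SyntheticConfig(seed=2, **base)).write(tmp_path / "b")
    assert _tree_digest(tmp_path / "a") != _tree_digest(tmp_path / "b")


def test_truth_occupancy_matches_generated_files(small_bundle):
    truth = small_bundle.truth
    for og, per_acc in truth.members.items():
        carriers = {acc for acc, genes in per_acc.items() if genes}
        assert len(carriers) == truth.occupancy[og]
        for acc, genes in per_acc.items():
            for g in genes:
                assert g in small_bundle.proteins[acc]
                assert g in small_bundle.cds[acc]


def test_every_gene_in_exactly_one_orthogroup(small_bundle):
    mapping = small_bundle.truth.gene_to_orthogroup()
    all_genes = {
        g for acc in small_bundle.accessions for g in small_bundle.proteins[acc]
    }
    assert set(mapping) == all_genes


def test_cloud_orthogroups_present_in_at_most_two_accessions():
    config = SyntheticConfig(n_accessions=20, n_core=3, n_softcore=2, n_shell=2,
                             n_cloud=5, n_background_genes=10, seed=3)
    bundle = generate_pangenome(config)
    cloud = [og for og, lab in bundle.truth.occupancy_class.items() if lab == "cloud"]
    assert len(cloud) == 5
    for og in cloud:
        assert bundle.truth.occupancy[og] <= 2


def test_protein_is_translation_of_cds(small_bundle):
    acc = small_bundle.accessions[0]
    for gene, cds in list(small_bundle.cds[acc].items())[:5]:
        assert cds[:3] == "ATG"
        assert cds[-3:] in STOP_CODONS
        translated = "".join(
            GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3)
        )
        assert translated == small_bundle.proteins[acc][gene]


def test_impossible_softcore_request_raises():
    config = SyntheticConfig(n_accessions=5, n_core=2, n_softcore=3, n_shell=0, n_cloud=0)
    with pytest.raises(SyntheticConfigError):
        generate_pangenome(config)


def test_invalid_identity_ordering_raises():
    with pytest.raises(SyntheticConfigError):
        SyntheticConfig(within_group_identity=0.96, between_group_identity=0.5,
                        dispensable_extra_divergence=0.0).validate()
        SyntheticConfig(within_group_identity=0.96, between_group_identity=0.97).validate()


class TestMutateProtein:
    def test_target_one_returns_unchanged(self):
        seq = "MKVLLLAAAWERTY" * 10
        assert mutate_protein(seq, 1.0, seed=1) == seq

    def test_target_realized_within_tolerance(self, rng):
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 200))
        mutated = mutate_protein(seq, 0.97, seed=5)
        identical = sum(a == b for a, b in zip(seq, mutated))
        assert 190 <= identical <= 198  # 194 +/- 4

    def test_target_zero_gives_low_identity(self):
        seq = "A" * 150
        mutated = mutate_protein(seq, 0.0, seed=2)
        identity = sum(a == b for a, b in zip(seq, mutated)) / 150
        assert identity <= 0.1

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            mutate_protein("", 0.9, seed=0)


class TestGenerateCdsWithBias:
    def test_structure(self):
        cds = generate_cds_with_bias(200, 0.5, seed=1)
        assert len(cds) == 600
        assert cds[:3] == "ATG"
        assert cds[-3:] in STOP_CODONS
        internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
        assert not any(c in STOP_CODONS for c in internal)

    def test_gc3_extreme_high(self):
        cds = generate_cds_with_bias(300, 1.0, seed=2)
        comp = third_position_composition(count_codons(cds))
        assert comp["gc3s"] == 1.0

    def test_gc3_mid_realized(self):
        cds = generate_cds_with_bias(1000, 0.5, seed=3)
        comp = third_position_composition(count_codons(cds))
        assert 0.47 <= comp["gc3s"] <= 0.53

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            generate_cds_with_bias(1, 0.5, seed=0)


class TestTimecourse:
    def test_zero_noise_gives_identical_cluster_profiles(self):
        df, labels = generate_timecourse_expression(12, 3, 0.0, seed=1)
        # remove per-gene scale/offset: z-score rows, then compare in-cluster
        z = df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=0), axis=0)
        for c in range(3):
            rows = z.loc[labels[labels == c].index].to_numpy()
            assert np.allclose(rows, rows[0], atol=1e-9)

    def test_row_count_and_labels(self):
        df, labels = generate_timecourse_expression(25, 4, 0.1, seed=2)
        assert df.shape == (25, 4)
        assert len(labels) == 25
        assert set(labels) == {0, 1, 2, 3}

    def test_more_clusters_than_genes_raises(self):
        with pytest.raises(ValueError):
            generate_timecourse_expression(3, 5, 0.1, seed=0)


class TestPlantMotifs:
    @pytest.fixture()
    def pwm(self):
        counts = np.full((4, 6), 1.0)
        for j, b in enumerate("ACGTAC"):
            counts["ACGT".index(b), j] = 40.0
        return Pwm("toy", counts)

    def test_zero_sites_leaves_promoters_unchanged(self, pwm):
        proms = {"p1": "ACGT" * 30, "p2": "TTTT" * 30}
        out, sites = plant_motifs(proms, pwm, 0, seed=1)
        assert out == proms and sites == []

    def test_planted_word_at_recorded_offset(self, pwm):
        proms = {"p1": "T" * 120}
        out, sites = plant_motifs(proms, pwm, 1, seed=1)
        (pid, off), = sites
        assert out[pid][off : off + pwm.width] == pwm.consensus

    def test_capacity_exceeded_raises(self, pwm):
        with pytest.raises(ValueError):
            plant_motifs({"p1": "A" * 50}, pwm, 2, seed=0)
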