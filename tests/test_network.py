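"""Co-expression edges, PWM scanning and GO enrichment."""

import numpy as np
import pandas as pd
import pytest

from panfam.network import (
    CoexpressionEdge,
    MotifHit,
    Pwm,
    assemble_network,
    enrich,
    pearson_edges,
    pwm_scan,
)
from panfam.network import _score_distribution

from _oracles import hypergeom_upper_tail_oracle, pwm_pvalues_oracle


def _expr(rows):
    n = len(next(iter(rows.values())))
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"c{i}" for i in range(n)])


class TestPearsonEdges:
    def test_identical_profiles_make_an_edge(self):
        expr = _expr({"f": [1.0, 2, 3, 4, 5, 6], "t": [2.0, 4, 6, 8, 10, 12]})
        (edge,) = pearson_edges(expr, ["f"])
        assert edge.target == "t" and edge.r == pytest.approx(1.0)

    def test_r_below_threshold_excluded(self, rng):
        # construct a target with r ~ 0.85 against the focal profile
        base = rng.normal(size=30)
        noisy = 0.85 * base + np.sqrt(1 - 0.85**2) * rng.normal(size=30)
        r = np.corrcoef(base, noisy)[0, 1]
        assert r < 0.9  # p would easily pass at n=30; r gate must exclude
        edges = pearson_edges(_expr({"f": base, "t": noisy}), ["f"])
        assert edges == []

    def test_p_matches_permutation_estimate(self, rng):
        base = rng.normal(size=10)
        other = 0.5 * base + rng.normal(size=10)
        expr = _expr({"f": base, "t": other})
        edges = pearson_edges(expr, ["f"], r_min=-1.1, p_max=1.1)
        p_t = edges[0].p
        r_obs = abs(np.corrcoef(base, other)[0, 1])
        hits = 0
        n_perm = 4000
        for _ in range(n_perm):
            r = np.corrcoef(base, rng.permutation(other))[0, 1]
            hits += abs(r) >= r_obs
        p_perm = hits / n_perm
        assert p_t == pytest.approx(p_perm, abs=0.03)

    def test_zero_variance_rows_skipped_with_warning(self):
        expr = _expr({"f": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning):
            edges = pearson_edges(expr, ["f"], r_min=-1.1, p_max=1.1)
        assert edges == []

    def test_too_few_columns_raise(self):
        with pytest.raises(ValueError):
            pearson_edges(_expr({"f": [1.0, 2], "t": [2.0, 1]}), ["f"])


def _toy_pwm(consensus="ACGTA", strength=30.0):
    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strength
    return Pwm("toy", counts)


class TestPwmScan:
    def test_score_distribution_sums_to_one(self):
        pwm = _toy_pwm()
        q = np.rint(pwm.log_odds() / 1e-3).astype(np.int64)
        dist, _ = _score_distribution(q, pwm.background)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_consensus_hit_found_at_planted_offset(self, rng):
        pwm = _toy_pwm("ACGTACGT")
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        seq = seq[:37] + pwm.consensus + seq[37 + pwm.width :]
        hits = pwm_scan({"p": seq}, pwm, p_max=1e-3)
        offsets = {h.offset for h in hits if h.strand == "+"}
        assert 37 in offsets
        best = max(hits, key=lambda h: h.score)
        assert best.offset == 37 or best.score == pytest.approx(
            max(h.score for h in hits)
        )

    def test_reverse_complement_reported_on_minus_strand(self):
        pwm = _toy_pwm("AACGTG")
        rc = "CACGTT"
        seq = "T" * 20 + rc + "T" * 20
        hits = pwm_scan({"p": seq}, pwm, p_max=1e-2)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.offset == 20 for h in minus)
        plus_score = max(h.score for h in minus)
        fwd_hits = pwm_scan({"q": "T" * 20 + pwm.consensus + "T" * 20}, pwm, p_max=1e-2)
        assert plus_score == pytest.approx(max(h.score for h in fwd_hits))

    def test_pvalues_match_word_enumeration_oracle(self):
        pwm = _toy_pwm("ACGTA", strength=12.0)
        oracle = pwm_pvalues_oracle(pwm)
        seq = "ACGTA" + "GGTAC" + "TTTTT"
        hits = pwm_scan({"p": seq}, pwm, p_max=1.0)
        lo = pwm.log_odds()
        q = np.rint(lo / 1e-3).astype(int)
        for h in hits:
            if h.strand != "+":
                continue
            window = seq[h.offset : h.offset + 5]
            score = sum(int(q["ACGT".index(b), j]) for j, b in enumerate(window))
            assert h.p == pytest.approx(oracle[score], abs=1e-12)

    def test_pvalue_monotone_in_score(self, rng):
        pwm = _toy_pwm("ACGTAC")
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        hits = pwm_scan({"p": seq}, pwm, p_max=1.0)
        hits.sort(key=lambda h: h.score)
        for h1, h2 in zip(hits, hits[1:]):
            assert h1.p >= h2.p

    def test_short_promoter_skipped_with_warning(self):
        pwm = _toy_pwm("ACGTACGT")
        with pytest.warns(UserWarning):
            hits = pwm_scan({"tiny": "ACG"}, pwm, p_max=1.0)
        assert hits == []


class TestEnrich:
    def test_exact_extreme_case(self):
        bg = [f"g{i}" for i in range(20)]
        term_map = {g: ["GO:X"] for g in bg[:5]}
        fg = bg[:5]
        df = enrich(fg, bg, term_map)
        row = df[df["term_id"] == "GO:X"].iloc[0]
        assert row["p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_matches_combinatorial_oracle(self, rng):
        bg = [f"g{i}" for i in range(18)]
        term_map = {g: ["GO:A"] for g in bg[:7]}
        fg = bg[3:9]
        df = enrich(fg, bg, term_map)
        row = df[df["term_id"] == "GO:A"].iloc[0]
        want = hypergeom_upper_tail_oracle(int(row["k"]), 18, 7, 6)
        assert row["p"] == pytest.approx(want, rel=1e-9)

    def test_bh_preserves_p_ordering(self):
        bg = [f"g{i}" for i in range(30)]
        term_map = {}
        for i, g in enumerate(bg):
            terms = []
            if i < 10:
                terms.append("GO:strong")
            if i % 2 == 0:
                terms.append("GO:weak")
            terms.append("GO:all")
            term_map[g] = terms
        df = enrich(bg[:8], bg, term_map)
        assert df["p"].is_monotonic_increasing
        assert (df["fdr"].to_numpy()[np.argsort(df["p"].to_numpy())] ==
                np.sort(df["fdr"].to_numpy())).all() or df["fdr"].is_monotonic_increasing

    def test_equal_p_values_share_bh_value(self):
        bg = [f"g{i}" for i in range(12)]
        term_map = {bg[0]: ["GO:a"], bg[1]: ["GO:b"]}
        df = enrich(bg[:6], bg, term_map)
        assert df["p"].nunique() == 1
        assert df["fdr"].nunique() == 1

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError):
            enrich([], ["g1"], {})


class TestAssembleNetwork:
    def _edges(self):
        return [
            CoexpressionEdge("nac1", "t_hit", 0.95, 1e-4),
            CoexpressionEdge("nac1", "t_nohit", 0.97, 1e-5),
        ]

    def _hits(self):
        return [MotifHit("t_hit", 10, "+", 12.0, 1e-6),
                MotifHit("t_lowr", 20, "+", 11.0, 1e-6)]

    def test_requires_both_edge_and_motif(self):
        nodes, edges, _ = assemble_network(self._edges(), self._hits())
        assert set(edges["target"]) == {"t_hit"}
        assert "t_nohit" not in set(nodes["node"])
        assert "t_lowr" not in set(nodes["node"])

    def test_per_cluster_counts(self):
        labels = {"t_hit": 2, "nac1": 2}
        _, _, per_cluster = assemble_network(self._edges(), self._hits(), labels)
        assert per_cluster.to_dict() == {2: 1}

    def test_planted_targets_recovered_from_bundle(self, small_bundle):
        tc = small_bundle.timecourse_expression
        focal = [
            g for g in tc.index
            if any(g in small_bundle.cds[a] for a in small_bundle.accessions)
        ]
        from panfam.expression import filter_and_standardize

        std = filter_and_standardize(tc)
        edges = pearson_edges(tc.loc[std.index], [g for g in focal if g in std.index])
        promoters = small_bundle.promoters
        hits = pwm_scan(promoters, small_bundle.pwm, p_max=1e-6)
        _, edge_df, _ = assemble_network(edges, hits)
        retained = set(edge_df["target"])
        planted = set(small_bundle.truth.regulated_targets)
        assert planted <= retained
        # at the stringent motif threshold, chance co-occurrence is rare
        assert len(retained - planted) <= 2
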