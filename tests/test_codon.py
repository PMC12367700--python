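"""Codon usage bias suite: RSCU, ENC, CAI, third-position statistics."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panfam.codon import (
    GENETIC_CODE,
    SINGLE_CODON_AA,
    SYNONYMOUS_FAMILIES,
    CodonCounts,
    cai,
    codon_profile,
    count_codons,
    enc,
    enc_expected,
    gc_content,
    optimal_codons,
    rscu,
    third_position_composition,
)
from panfam.synth import generate_cds_with_bias

from _oracles import enc_oracle


class TestCountCodons:
    def test_counts_and_terminal_stop_exclusion(self):
        c = count_codons("ATGAAATAG")
        assert dict(c.counts) == {"ATG": 1, "AAA": 1}
        assert c.n_codons == 2

    def test_ambiguous_codons_are_skipped(self):
        c = count_codons("ATGNNNAAA")
        assert c.n_codons == 2 and c.n_skipped == 1

    def test_internal_stop_raises(self):
        with pytest.raises(ValueError, match="stop"):
            count_codons("ATGTAGAAA")

    def test_bad_length_raises(self):
        with pytest.raises(ValueError):
            count_codons("ATGA")


class TestRscu:
    def test_equal_usage_gives_one(self):
        values = rscu(Counter({"GAA": 2, "GAG": 2}))
        assert values["GAA"] == values["GAG"] == 1.0

    def test_skewed_usage(self):
        values = rscu(Counter({"GAA": 3, "GAG": 1}))
        assert values["GAA"] == 1.5 and values["GAG"] == 0.5

    def test_unobserved_family_absent_and_singletons_excluded(self):
        values = rscu(Counter({"ATG": 5}))
        assert values == {}

    @given(st.lists(st.sampled_from(sorted(GENETIC_CODE)), min_size=10, max_size=200))
    def test_family_sums_equal_family_size(self, codons):
        values = rscu(Counter(codons))
        for aa, family in SYNONYMOUS_FAMILIES.items():
            if aa in SINGLE_CODON_AA:
                continue
            observed = [c for c in family if c in values]
            if observed:
                assert sum(values[c] for c in family) == pytest.approx(len(family))


class TestEnc:
    def test_single_codon_per_family_gives_twenty(self):
        counts = Counter()
        for aa, family in SYNONYMOUS_FAMILIES.items():
            counts[family[0]] = 50
        assert enc(counts) == 20.0

    def test_uniform_usage_reaches_sixty_one(self):
        counts = Counter({codon: 1000 for codon in GENETIC_CODE})
        assert enc(counts) == 61.0

    def test_skew_reduces_enc(self):
        uniform = Counter({codon: 100 for codon in GENETIC_CODE})
        skewed = Counter(uniform)
        for aa, family in SYNONYMOUS_FAMILIES.items():
            if len(family) > 1:
                skewed[family[0]] += 90 * (len(family) - 1)
                for c in family[1:]:
                    skewed[c] -= 90
        assert enc(skewed) < enc(uniform)

    def test_matches_formula_oracle_on_random_counts(self, rng):
        for _ in range(30):
            counts = Counter(
                {c: int(k) for c, k in zip(sorted(GENETIC_CODE), rng.integers(0, 30, 61))}
            )
            got = enc(counts)
            want = enc_oracle(counts)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_all_singleton_counts_are_na(self):
        assert math.isnan(enc(Counter({"GAA": 1, "TTT": 1})))


class TestEncExpected:
    @pytest.mark.parametrize("s,value", [(0.5, 60.5), (1e-12, 31.0), (1 - 1e-12, 32.0)])
    def test_closed_form_values(self, s, value):
        assert enc_expected(s) == pytest.approx(value, abs=1e-6)


class TestCai:
    def _reference(self):
        # two-family toy reference: Glu prefers GAA 3:1, Lys prefers AAA 4:1
        return [CodonCounts("ref", Counter({"GAA": 30, "GAG": 10, "AAA": 40, "AAG": 10}), 90)]

    def test_gene_of_preferred_codons_scores_one(self):
        gene = CodonCounts("g", Counter({"GAA": 5, "AAA": 3}), 8)
        assert cai(gene, self._reference()) == pytest.approx(1.0)

    def test_hand_computed_toy_value(self):
        # w(GAG) = (0.5/1.5), w(AAG) = (0.4/1.6); CAI = sqrt(w_GAG * w_AAG)
        gene = CodonCounts("g", Counter({"GAG": 1, "AAG": 1}), 2)
        expected = math.sqrt((0.5 / 1.5) * (0.4 / 1.6))
        assert cai(gene, self._reference()) == pytest.approx(expected, abs=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        ref = self._reference()
        for _ in range(10):
            codons = rng.choice(["GAA", "GAG", "AAA", "AAG"], size=20)
            gene = CodonCounts("g", Counter(codons.tolist()), 20)
            value = cai(gene, ref)
            assert 0.0 < value <= 1.0

    def test_scale_invariance_of_reference(self):
        gene = CodonCounts("g", Counter({"GAG": 2, "AAA": 1}), 3)
        ref = self._reference()
        scaled = [CodonCounts("r", Counter({k: 7 * v for k, v in ref[0].counts.items()}), 0)]
        assert cai(gene, ref) == pytest.approx(cai(gene, scaled), abs=1e-12)

    def test_gene_without_scorable_codons_is_na(self):
        gene = CodonCounts("g", Counter({"ATG": 3, "TGG": 2}), 5)
        assert math.isnan(cai(gene, self._reference()))


class TestThirdPosition:
    def test_balanced_a3_t3_centers_pr2(self):
        comp = third_position_composition(Counter({"GGA": 5, "GGT": 5}))
        assert comp["pr2_y"] == 0.5

    def test_all_gc_third_positions(self):
        comp = third_position_composition(Counter({"GGG": 3, "GGC": 2, "GAG": 1}))
        assert comp["gc3s"] == 1.0

    def test_hand_tallied_gene(self):
        # GGA, GGT, GGC -> third positions A, T, C over variable codons;
        # ATG (Met) excluded
        comp = third_position_composition(Counter({"GGA": 1, "GGT": 1, "GGC": 1, "ATG": 4}))
        assert comp["a3s"] == pytest.approx(1 / 3)
        assert comp["t3s"] == pytest.approx(1 / 3)
        assert comp["gc3s"] == pytest.approx(1 / 3)
        assert comp["pr2_x"] == 0.0  # G3=0 among variable codons
        assert comp["pr2_y"] == 0.5

    def test_zero_denominator_is_na(self):
        comp = third_position_composition(Counter({"ATG": 2}))
        assert math.isnan(comp["gc3s"]) and math.isnan(comp["pr2_x"])


class TestSuiteProperties:
    def test_profile_is_input_order_invariant(self, rng):
        genes = [generate_cds_with_bias(150, 0.3 + 0.05 * i, seed=i) for i in range(12)]
        counts = [count_codons(g, gene_id=f"g{i}") for i, g in enumerate(genes)]
        opt_fwd = optimal_codons(counts, tail=0.25)
        opt_rev = optimal_codons(list(reversed(counts)), tail=0.25)
        assert opt_fwd.equals(opt_rev)

    def test_gc_content_matches_direct_count(self):
        cds = "ATGGGCAAATAA"
        counted = count_codons(cds)
        body = cds[:-3]
        assert gc_content(counted) == pytest.approx(
            sum(b in "GC" for b in body) / len(body)
        )

    def test_pr2_centers_on_balanced_corpus(self, rng):
        # sample codons uniformly within four-fold boxes, where third-position
        # parity holds by construction; PR2 must center on (0.5, 0.5)
        four_fold = [
            fam for fam in SYNONYMOUS_FAMILIES.values() if len(fam) == 4
        ]
        xs, ys = [], []
        for _ in range(40):
            counts = Counter()
            for fam in four_fold:
                draws = rng.multinomial(120, [0.25] * 4)
                for codon, k in zip(fam, draws):
                    counts[codon] += int(k)
            comp = third_position_composition(counts)
            xs.append(comp["pr2_x"])
            ys.append(comp["pr2_y"])
        assert abs(np.mean(xs) - 0.5) < 0.02
        assert abs(np.mean(ys) - 0.5) < 0.02


class TestOptimalCodons:
    def test_flags_follow_the_delta_rule(self):
        # the low-bias (high-ENC) set mildly avoids each family's first
        # codon; the high-bias (low-ENC) set strongly prefers it
        disfavoring = Counter()
        preferring = Counter({c: 1 for c in GENETIC_CODE})
        for fam in SYNONYMOUS_FAMILIES.values():
            if len(fam) == 1:
                disfavoring[fam[0]] = 10
                continue
            disfavoring[fam[0]] = 6
            for c in fam[1:]:
                disfavoring[c] = 12
            preferring[fam[0]] += 60
        low_bias = [
            CodonCounts(f"u{i}", disfavoring, sum(disfavoring.values()))
            for i in range(9)
        ]
        high_bias = [
            CodonCounts(f"b{i}", preferring, sum(preferring.values()))
            for i in range(9)
        ]
        report = optimal_codons(low_bias + high_bias, tail=0.4)
        flagged = set(report.index[report["is_optimal"]])
        planted = {fam[0] for fam in SYNONYMOUS_FAMILIES.values() if len(fam) > 1}
        assert flagged == {
            c
            for c in planted
            if report.loc[c, "rscu_high"] > 1
            and report.loc[c, "rscu_low"] < 1
            and report.loc[c, "delta_rscu"] >= 0.3
        }
        assert flagged  # the planted preferred codons are found
        sub = report.dropna()
        assert sub[(sub["delta_rscu"] < 0.3) & sub["is_optimal"]].empty
        assert not sub[~sub.index.isin(planted) & sub["is_optimal"]].shape[0]

    def test_too_few_genes_raise(self):
        counts = [CodonCounts("g", Counter({"GAA": 5, "GAG": 1}), 6)] * 5
        with pytest.raises(ValueError):
            optimal_codons(counts)
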