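"""Quality filtering, final scores, compound-het pairing, phenotype fusion,
inheritance filtering, ranking and pathogenic counting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mendelrank.models import ClassProbabilities
from mendelrank.prioritization import (
    UNRANKED,
    CandidateMode,
    CandidateScore,
    InheritancePattern,
    PhenoScoreTable,
    VariantCall,
    Zygosity,
    count_pathogenic,
    final_scores,
    fuse_phenotype,
    gado_transform,
    harmonic_mean,
    inheritance_filter,
    quality_filter,
    rank,
    rank_of,
    select_hpo_terms,
)


def call(vid="v1", gene="G1", zyg=Zygosity.HET, probs=(0.1, 0.7, 0.2),
         hap=None, depth=40, alt=20, ref=20, af=0.0, cf=0.0):
    return VariantCall(vid, gene, zyg, ClassProbabilities(*probs),
                       haplotype_group=hap, depth=depth, alt_reads=alt,
                       ref_reads=ref, pop_af=af, cohort_freq=cf)


class TestQualityFilter:
    @pytest.mark.parametrize("depth,keep", [(19, False), (20, True)])
    def test_depth_boundary(self, depth, keep):
        assert quality_filter(call(depth=depth)) is keep

    def test_het_allele_balance_boundary(self):
        assert quality_filter(call(ref=40, alt=20))          # alt == ref/2
        assert not quality_filter(call(ref=40, alt=19))

    def test_hom_calls_skip_allele_balance(self):
        assert quality_filter(call(zyg=Zygosity.HOM, ref=40, alt=5))

    @pytest.mark.parametrize("af,keep", [(0.02, False), (0.01, True)])
    def test_population_frequency_boundary(self, af, keep):
        assert quality_filter(call(af=af)) is keep

    def test_cohort_frequency_filter(self):
        assert not quality_filter(call(cf=0.5))


class TestFinalScores:
    def test_het_uses_dominant_hom_uses_recessive(self):
        cands = final_scores([call(probs=(0.1, 0.7, 0.2)),
                              call(vid="v2", zyg=Zygosity.HOM,
                                   probs=(0.1, 0.2, 0.7))])
        scores = {c.candidate_id: (c.mode, c.final_score) for c in cands}
        assert scores[("v1",)] == (CandidateMode.DOMINANT_HET, pytest.approx(0.7))
        assert scores[("v2",)] == (CandidateMode.RECESSIVE_HOM, pytest.approx(0.7))

    def test_comphet_harmonic_mean_example(self):
        cands = final_scores([
            call(vid="a", probs=(0.1, 0.1, 0.8)),
            call(vid="b", probs=(0.2, 0.4, 0.4)),
        ])
        ch = [c for c in cands if c.mode is CandidateMode.RECESSIVE_COMPHET]
        assert len(ch) == 1
        assert ch[0].final_score == pytest.approx(2 * 0.8 * 0.4 / (0.8 + 0.4))
        assert ch[0].candidate_id == ("a", "b")

    def test_equal_recessive_scores_match_homozygote(self):
        r = 0.61
        cands = final_scores([
            call(vid="a", probs=(0.3, 0.09, r)),
            call(vid="b", probs=(0.3, 0.09, r)),
        ])
        ch = [c for c in cands if c.mode is CandidateMode.RECESSIVE_COMPHET][0]
        assert ch.final_score == pytest.approx(r)

    def test_same_haplotype_pairs_excluded(self):
        cands = final_scores([
            call(vid="a", hap=1), call(vid="b", hap=1), call(vid="c", hap=2),
        ])
        pairs = {c.candidate_id for c in cands
                 if c.mode is CandidateMode.RECESSIVE_COMPHET}
        assert pairs == {("a", "c"), ("b", "c")}

    def test_comphet_count_is_choose2_minus_same_haplotype(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 8))
            haps = rng.integers(0, 3, size=n)
            calls = [call(vid=f"v{i}", hap=int(haps[i])) for i in range(n)]
            cands = final_scores(calls)
            n_pairs = sum(1 for c in cands
                          if c.mode is CandidateMode.RECESSIVE_COMPHET)
            same = sum(1 for i, j in itertools.combinations(range(n), 2)
                       if haps[i] == haps[j])
            assert n_pairs == n * (n - 1) // 2 - same

    def test_blacklisted_variants_dropped(self):
        cands = final_scores([call(vid="bad"), call(vid="ok")],
                             blacklist=["bad"])
        assert {c.candidate_id for c in cands} == {("ok",)}


class TestHarmonicMean:
    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_identity(self, a, b):
        hm = harmonic_mean(a, b)
        assert min(a, b) - 1e-12 <= hm <= max(a, b) + 1e-12
        assert harmonic_mean(a, a) == pytest.approx(a)

    def test_monotone_in_each_argument_over_random_pairs(self):
        rng = np.random.default_rng(1)
        pairs = rng.uniform(0, 1, size=(10000, 2))
        eps = 1e-3
        for a, b in pairs:
            assert harmonic_mean(a + eps, b) >= harmonic_mean(a, b) - 1e-12
        assert harmonic_mean(0.0, 0.0) == 0.0


class TestPhenotypeFusion:
    def test_arithmetic_mean(self):
        c = CandidateScore(("v",), "G1", CandidateMode.DOMINANT_HET, 0.8)
        fused = fuse_phenotype(c, PhenoScoreTable({"G1": 0.6}))
        assert fused.fused_score == pytest.approx(0.7)
        assert fused.final_score == pytest.approx(0.8)  # untouched

    def test_absent_gene_defaults_to_half(self):
        c = CandidateScore(("v",), "MISSING", CandidateMode.DOMINANT_HET, 0.8)
        assert fuse_phenotype(c, PhenoScoreTable({})).fused_score == \
            pytest.approx(0.65)

    def test_constant_table_preserves_ranking_order(self):
        rng = np.random.default_rng(2)
        cands = [CandidateScore((f"v{i}",), f"G{i}",
                                CandidateMode.DOMINANT_HET,
                                float(rng.uniform(0, 1))) for i in range(50)]
        table = PhenoScoreTable({f"G{i}": 0.5 for i in range(50)})
        fused = [fuse_phenotype(c, table) for c in cands]
        base_order = [c.candidate_id for c in rank(cands)]
        fused_order = [c.candidate_id for c in rank(fused, use_fused=True)]
        assert base_order == fused_order

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PhenoScoreTable({"G1": 1.5})


class TestGadoTransform:
    def test_zero_z_maps_to_half(self):
        t = gado_transform(np.zeros((3, 2)), genes=["a", "b", "c"])
        assert t["a"] == pytest.approx(0.5)

    def test_known_association_scores_logistic_of_three(self):
        z = np.zeros((1, 1))
        t = gado_transform(z, known=np.ones((1, 1), bool), genes=["g"])
        assert t["g"] == pytest.approx(1 / (1 + np.exp(-3.0)), abs=1e-9)

    def test_term_set_score_is_mean(self):
        # logistic^-1(0.4), logistic^-1(0.8) as the two term scores
        z = np.array([[np.log(0.4 / 0.6), np.log(0.8 / 0.2)]])
        t = gado_transform(z, genes=["g"])
        assert t["g"] == pytest.approx(0.6)

    def test_missing_gene_scores_half(self):
        t = gado_transform(np.zeros((1, 1)), genes=["g"])
        assert t["nope"] == 0.5

    def test_empty_term_set_errors(self):
        with pytest.raises(ValueError):
            gado_transform(np.zeros((2, 3)), term_indices=[])

    def test_hpo_term_cap_is_seeded(self):
        terms = [f"HP:{i:07d}" for i in range(9)]
        a = select_hpo_terms(terms, max_terms=5, seed=3)
        assert a == select_hpo_terms(terms, max_terms=5, seed=3)
        assert len(a) == 5 and set(a) <= set(terms)
        assert select_hpo_terms(terms[:4]) == terms[:4]


class TestInheritanceFilterAndRank:
    def make_cands(self):
        return [
            CandidateScore(("d",), "G1", CandidateMode.DOMINANT_HET, 0.9),
            CandidateScore(("h",), "G2", CandidateMode.RECESSIVE_HOM, 0.8),
            CandidateScore(("a", "b"), "G3", CandidateMode.RECESSIVE_COMPHET, 0.7),
        ]

    def test_dominant_filter_keeps_only_het_candidates(self):
        kept = inheritance_filter(self.make_cands(), InheritancePattern.DOMINANT)
        assert [c.mode for c in kept] == [CandidateMode.DOMINANT_HET]

    def test_recessive_filter_keeps_hom_and_comphet(self):
        kept = inheritance_filter(self.make_cands(), InheritancePattern.RECESSIVE)
        assert {c.mode for c in kept} == {CandidateMode.RECESSIVE_HOM,
                                          CandidateMode.RECESSIVE_COMPHET}

    def test_unknown_mode_is_identity(self):
        cands = self.make_cands()
        assert inheritance_filter(cands, InheritancePattern.UNKNOWN) == cands

    def test_recessive_filter_on_dominant_only_list_is_empty(self):
        only_dom = [self.make_cands()[0]]
        assert inheritance_filter(only_dom, InheritancePattern.RECESSIVE) == []

    def test_rank_descending_with_deterministic_ties(self):
        cands = [CandidateScore((f"v{i}",), "G", CandidateMode.DOMINANT_HET, s)
                 for i, s in enumerate([0.5, 0.9, 0.5, 0.1])]
        for _ in range(3):
            ordered = rank(cands)
            assert [c.candidate_id for c in ordered] == [
                ("v1",), ("v0",), ("v2",), ("v3",)]

    def test_rank_of_causal_top_score(self):
        cands = self.make_cands() + [
            CandidateScore(("causal",), "GX", CandidateMode.DOMINANT_HET, 1.0)]
        assert rank_of(cands, ["causal"]) == 1

    def test_comphet_pair_matches_either_member_order(self):
        cands = self.make_cands()
        assert rank_of(cands, ["b", "a"]) == rank_of(cands, ["a", "b"]) == 3

    def test_absent_causal_is_unranked(self):
        assert rank_of(self.make_cands(), ["ghost"]) == UNRANKED


class TestCountPathogenic:
    def test_zero_scores_count_nothing(self):
        cands = [CandidateScore(("v",), "G", CandidateMode.DOMINANT_HET, 0.0)]
        assert all(v == 0 for v in count_pathogenic(cands).values())

    def test_default_threshold_half(self):
        cands = [CandidateScore(("v",), "G", CandidateMode.DOMINANT_HET, 0.6),
                 CandidateScore(("w",), "G", CandidateMode.RECESSIVE_HOM, 0.5)]
        counts = count_pathogenic(cands)
        assert counts[CandidateMode.DOMINANT_HET] == 1
        assert counts[CandidateMode.RECESSIVE_HOM] == 0  # strict inequality

    def test_threshold_one_counts_nothing(self):
        cands = [CandidateScore(("v",), "G", CandidateMode.DOMINANT_HET, 1.0)]
        assert count_pathogenic(cands, threshold=1.0)[
            CandidateMode.DOMINANT_HET] == 0
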