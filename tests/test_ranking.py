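"""Term scores, KC ranks, decay/proximity, and answer ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import hypergeom_oracle

from grank.depth import assign_depths
from grank.lca_tcd import meaningful_candidates
from grank.model import (
    Aggregation,
    AnnotationSet,
    GoGraph,
    GrankError,
    MicroarrayReference,
    Query,
    RankParams,
    Relation,
    Term,
    map_query_to_kcs,
)
from grank.pog import Pog, build_pog
from grank.ranking import (
    KcRank,
    TermScore,
    combined_rank,
    hypergeom_score,
    kc_rank,
    proximity,
    rank_answers,
    rank_wrt_kc,
    score_terms,
    term_score,
)


class TestHypergeomScore:
    def test_small_exhaustive_example(self):
        # a=10, b=5, c=4, k=2: 55 of the C(10,4)=210 draws have <= 1 annotated
        assert hypergeom_score(10, 5, 4, 2) == pytest.approx(55 / 210, abs=1e-12)

    def test_k_zero_is_empty_sum(self):
        assert hypergeom_score(100, 40, 10, 0) == 0.0

    def test_saturates_at_one(self):
        # k - 1 >= min(b, c) covers the whole support
        assert hypergeom_score(20, 5, 10, 6) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_k(self):
        vals = [hypergeom_score(50, 20, 10, k) for k in range(11)]
        assert vals == sorted(vals)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exact_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(2, 200))
        b = int(rng.integers(0, a + 1))
        c = int(rng.integers(0, a + 1))
        k = int(rng.integers(0, min(b, c) + 1))
        assert hypergeom_score(a, b, c, k) == pytest.approx(
            float(hypergeom_oracle(a, b, c, k)), abs=1e-10
        )

    def test_parameter_violations(self):
        with pytest.raises(GrankError):
            hypergeom_score(10, 11, 4, 2)
        with pytest.raises(GrankError):
            hypergeom_score(10, 5, 4, -1)


class TestTermScore:
    def test_intersection_with_universe(self):
        ann = AnnotationSet()
        for g in ("g1", "g2", "outside"):
            ann.add(g, "GO:X")
        ref = MicroarrayReference(
            frozenset({"g1", "g2", "g3", "g4"}), frozenset({"g1", "g3"})
        )
        # b=2 (outside dropped), k=1, a=4, c=2
        expected = hypergeom_score(4, 2, 2, 1)
        assert term_score(ref, ann, "GO:X").s == pytest.approx(expected)

    def test_term_absent_from_universe_scores_zero(self):
        ann = AnnotationSet()
        ann.add("outside", "GO:X")
        ref = MicroarrayReference(frozenset({"g1"}), frozenset())
        assert term_score(ref, ann, "GO:X").s == 0.0


class TestKcRank:
    def make_chain(self):
        g = GoGraph(
            [Term("child"), Term("kc"), Term("parent")],
            [
                ("child", "kc", Relation.PART_OF),
                ("kc", "parent", Relation.PART_OF),
            ],
        )
        return build_pog(g, partof_transitivity=False)

    def test_hand_evaluated_chain(self):
        pog = self.make_chain()
        scores = {
            "child": TermScore("child", 0.2),
            "kc": TermScore("kc", 0.5),
            "parent": TermScore("parent", 0.8),
        }
        r = kc_rank(pog, "kc", scores, RankParams())
        # (1-p1-p2)=0; parents: 0.8/Ni(parent)=0.8/1; children: 0.2/Ni(child)=0.2/1
        assert r.r == pytest.approx(0.4 * 0.8 + 0.6 * 0.2)
        r2 = kc_rank(pog, "kc", scores, RankParams(p1=0.2, p2=0.3))
        assert r2.r == pytest.approx(0.5 * 0.5 + 0.2 * 0.8 + 0.3 * 0.2)

    def test_default_params_ignore_own_score(self):
        pog = self.make_chain()
        for s_kc in (0.0, 0.5, 1.0):
            scores = {
                "child": TermScore("child", 0.2),
                "kc": TermScore("kc", s_kc),
                "parent": TermScore("parent", 0.8),
            }
            assert kc_rank(pog, "kc", scores, RankParams()).r == pytest.approx(
                0.4 * 0.8 + 0.6 * 0.2
            )

    def test_isolated_kc(self):
        pog = Pog(frozenset({"kc"}), {})
        scores = {"kc": TermScore("kc", 0.9)}
        p = RankParams(p1=0.25, p2=0.25)
        assert kc_rank(pog, "kc", scores, p).r == pytest.approx(0.5 * 0.9)


class TestDecayAndAggregation:
    def test_adjacent_level_is_identity(self):
        assert rank_wrt_kc(KcRank("t", 0.42), 1, RankParams()) == pytest.approx(0.42)

    def test_decay_default(self):
        assert rank_wrt_kc(KcRank("t", 1.0), 2, RankParams()) == pytest.approx(0.7)
        assert rank_wrt_kc(KcRank("t", 2.0), 3, RankParams()) == pytest.approx(0.98)

    def test_monotone_in_levels(self):
        r = KcRank("t", 1.3)
        p = RankParams()
        vals = [rank_wrt_kc(r, j, p) for j in range(1, 8)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_j_below_one_rejected(self):
        with pytest.raises(GrankError):
            rank_wrt_kc(KcRank("t", 1.0), 0, RankParams())

    def test_combined_rank_identities(self):
        p_max = RankParams()
        p_sum = RankParams(aggregation=Aggregation.SUM)
        assert combined_rank([0.5], p_max) == combined_rank([0.5], p_sum) == 0.5
        assert combined_rank([0.2, 0.7, 0.4], p_max) == pytest.approx(0.7)
        assert combined_rank([0.2, 0.7, 0.4], p_sum) == pytest.approx(1.3)
        with pytest.raises(GrankError):
            combined_rank([], p_max)


class TestProximity:
    def test_coannotation_limit(self, fixture_depths):
        w = proximity(fixture_depths, {"GO:0072006"})
        assert w.height == w.width == 1 and w.prox == 1.0

    def test_two_terms_adjacent_columns(self):
        g = GoGraph(
            [Term(t) for t in ("A", "B", "C1", "C2", "D", "E")],
            [
                ("B", "A", Relation.IS_A),
                ("C1", "B", Relation.IS_A),
                ("C2", "B", Relation.IS_A),
                ("D", "C1", Relation.IS_A),
                ("E", "D", Relation.IS_A),
            ],
        )
        w = proximity(assign_depths(g), {"C2", "E"})
        assert (w.height, w.width) == (3, 2)
        assert w.prox == pytest.approx(1 / 6)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_prox_bounded(self, fixture_depths, data):
        terms = data.draw(
            st.sets(
                st.sampled_from(sorted(fixture_depths.depths)), min_size=1, max_size=6
            )
        )
        assert 0.0 < proximity(fixture_depths, terms).prox <= 1.0

    def test_empty_set_rejected(self, fixture_depths):
        with pytest.raises(GrankError):
            proximity(fixture_depths, set())


class TestRankAnswers:
    def run(self, bundle, genes, params=None):
        pog = build_pog(bundle.graph)
        depths = assign_depths(bundle.graph)
        q = Query(*genes)
        kcs = map_query_to_kcs(q, bundle.annotations)
        verdicts = meaningful_candidates(pog, depths, kcs)
        needed = {t for ts in kcs.values() for t in ts}
        for t in set(needed):
            needed |= pog.parents(t) | pog.children(t)
        scores = score_terms(bundle.microarray, bundle.annotations, needed)
        return rank_answers(
            verdicts, kcs, pog, depths, scores,
            params or RankParams(), bundle.annotations, q,
        )

    def test_example_answer_genes(self, bundle):
        ans = self.run(bundle, ("JAG1", "LHX1"))
        top = ans.rows[0]
        assert top.term == "GO:0048513"
        assert top.genes == ("Ci-FoxI-c", "FKH-4", "fkh-5")
        assert "Ssc.22980" not in ans.genes

    def test_example_answer_single_gene(self, bundle):
        ans = self.run(bundle, ("Gga.4082", "LHX1"))
        assert ans.genes == ("Ssc.22980",)

    def test_scores_finite_nonnegative_sorted(self, bundle):
        ans = self.run(bundle, ("JAG1", "LHX1", "Gga.4082"))
        scores = [r.score for r in ans]
        assert all(np.isfinite(s) and s >= 0 for s in scores)
        assert scores == sorted(scores, reverse=True)

    def test_query_order_invariance(self, bundle):
        a = self.run(bundle, ("JAG1", "LHX1"))
        b = self.run(bundle, ("LHX1", "JAG1"))
        assert a.rows == b.rows

    def test_no_decay_single_kc_collapses_to_sum(self):
        # decay=1, prox=1 (single shared KC), so score == sum of per-gene R(KC)
        g = GoGraph(
            [Term("R"), Term("T"), Term("U")],
            [
                ("T", "R", Relation.IS_A),
                ("U", "T", Relation.IS_A),
                ("U", "T", Relation.PART_OF),
            ],
        )
        pog, depths = build_pog(g), assign_depths(g)
        ann = AnnotationSet()
        ann.add("g1", "T")
        ann.add("g2", "T")
        ann.add("other", "U")
        ref = MicroarrayReference(frozenset({"g1", "g2", "other"}), frozenset({"other"}))
        params = RankParams(decay=1.0)
        q = Query("g1", "g2")
        kcs = map_query_to_kcs(q, ann)
        verdicts = meaningful_candidates(pog, depths, kcs)
        scores = score_terms(ref, ann, {"T", "U"})
        ans = rank_answers(verdicts, kcs, pog, depths, scores, params, ann, q)
        r_t = kc_rank(pog, "T", scores, params).r
        by_term = {row.term: row for row in ans}
        # the shared KC is its own sole candidate; both genes contribute R(T)
        assert set(by_term) == {"T"}
        assert by_term["T"].score == pytest.approx(2 * r_t)
        assert by_term["T"].genes == ()  # query genes excluded by default
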