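import itertools
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

import taxovote as tv
from taxovote.decision import (
    VotingParams,
    apply_min_support,
    build_weighted_tree,
    decide_all,
    decide_read,
    root_to_taxon,
)
from taxovote.errors import TaxovoteError, UnknownTaxonError
from taxovote.votes_io import ReadVotes

from conftest import votes


class TestVotingParams:
    def test_m_must_exceed_one(self):
        with pytest.raises(ValueError, match="m must be > 1"):
            VotingParams(3, m=1)
        with pytest.raises(ValueError):
            VotingParams(3, m=0.5)

    def test_m_accepts_float_exactly(self):
        assert VotingParams(3, m=2.5).m == Fraction(5, 2)

    def test_n_tools_positive(self):
        with pytest.raises(ValueError):
            VotingParams(0)


class TestWeightedTree:
    def test_two_species_one_genus(self, chain_tree):
        _, simp = chain_tree
        s1 = tv.species_nodes(simp)[0]
        g1 = simp.parent[s1]
        wt = build_weighted_tree(simp, [s1, s1, g1])
        assert wt.weight[s1] == 2
        assert wt.weight[g1] == 3
        assert all(wt.weight[a] == 3 for a in simp.lineage(g1))
        assert wt.weight[1] == wt.n_classified == 3

    def test_single_vote_all_ones(self, chain_tree):
        _, simp = chain_tree
        s1 = tv.species_nodes(simp)[0]
        wt = build_weighted_tree(simp, [s1])
        assert set(wt.weight) == set(simp.lineage(s1))
        assert set(wt.weight.values()) == {1}

    def test_disjoint_genera_share_family(self, simp):
        fam = next(t for t, r in simp.rank.items() if r is tv.Rank.FAMILY)
        g1, g2 = simp.children(fam)
        s1, s2 = simp.children(g1)[0], simp.children(g2)[0]
        wt = build_weighted_tree(simp, [s1, s2])
        assert wt.weight[fam] == 2
        assert wt.weight[s1] == wt.weight[s2] == 1

    def test_zero_vote_rejected(self, simp):
        with pytest.raises(ValueError):
            build_weighted_tree(simp, [0])

    def test_weight_monotone_root_to_leaf(self, simp):
        sp = tv.species_nodes(simp)
        wt = build_weighted_tree(simp, [sp[0], sp[3], sp[5], sp[5]])
        for node in wt.weight:
            for anc in simp.lineage(node)[:-1]:
                assert wt.weight[anc] >= wt.weight[node]


class TestRootToTaxon:
    def test_hand_counted_sums(self, chain_tree):
        # votes [s1, s1, g1]: six non-root ancestors of s1 (incl. g1)
        _, simp = chain_tree
        s1 = tv.species_nodes(simp)[0]
        g1 = simp.parent[s1]
        wt = build_weighted_tree(simp, [s1, s1, g1])
        assert root_to_taxon(wt, simp, s1) == 3 * 6 + 2 == 20
        assert root_to_taxon(wt, simp, g1) == 18

    def test_single_vote_equals_depth(self, chain_tree):
        _, simp = chain_tree
        s1 = tv.species_nodes(simp)[0]
        wt = build_weighted_tree(simp, [s1])
        assert root_to_taxon(wt, simp, s1) == simp.depth(s1) == 7

    def test_child_of_root_is_own_weight(self, simp):
        s1 = tv.species_nodes(simp)[0]
        sk = simp.lineage(s1)[1]
        wt = build_weighted_tree(simp, [s1, s1])
        assert root_to_taxon(wt, simp, sk) == wt.weight[sk] == 2

    def test_absent_node_is_lookup_error(self, simp):
        s1, s2 = tv.species_nodes(simp)[0], tv.species_nodes(simp)[-1]
        wt = build_weighted_tree(simp, [s1])
        with pytest.raises(UnknownTaxonError):
            root_to_taxon(wt, simp, s2)


P3 = VotingParams(3)


class TestDecideRead:
    def test_all_zero_sentinel(self, simp):
        d = decide_read(votes(0, 0, 0), simp, P3)
        assert (d.taxon, d.n_classified, d.n_support) == (0, 0, 3)
        assert d.score == 1

    def test_majority_species_vs_genus(self, chain_tree):
        _, simp = chain_tree
        s1 = tv.species_nodes(simp)[0]
        g1 = simp.parent[s1]
        d = decide_read(votes(s1, s1, g1), simp, P3)
        assert d.taxon == s1
        assert (d.n_classified, d.n_support) == (3, 2)
        assert d.score == Fraction(2, 3) - Fraction(1, 6) == Fraction(1, 2)

    def test_two_disjoint_species_meet_at_family(self, simp):
        fam = next(t for t, r in simp.rank.items() if r is tv.Rank.FAMILY)
        g1, g2 = simp.children(fam)
        s1, s2 = simp.children(g1)[0], simp.children(g2)[0]
        d = decide_read(votes(s1, s2, 0), simp, P3)
        assert d.taxon == fam
        assert (d.n_classified, d.n_support) == (2, 2)
        assert d.score == Fraction(2, 3)

    def test_single_tool_classifies(self, simp):
        s1 = tv.species_nodes(simp)[0]
        d = decide_read(votes(s1, 0, 0), simp, P3)
        assert d.taxon == s1
        assert (d.n_classified, d.n_support) == (1, 1)
        assert d.score == Fraction(1, 3)

    def test_unanimity(self, simp):
        s1 = tv.species_nodes(simp)[0]
        for n in (2, 3, 5):
            d = decide_read(
                ReadVotes("r", (s1,) * n), simp, VotingParams(n)
            )
            assert d.taxon == s1 and d.n_support == n and d.score == 1

    def test_cross_superkingdom_votes_decide_root(self, simp):
        species = tv.species_nodes(simp)
        s_left, s_right = species[0], species[-1]  # different superkingdoms
        d = decide_read(votes(s_left, s_right, 0), simp, P3)
        assert d.taxon == 1
        assert d.n_support == d.n_classified == 2
        assert d.score == Fraction(2, 3)

    def test_n_mismatch_rejected(self, simp):
        with pytest.raises(TaxovoteError, match="N=3"):
            decide_read(votes(0, 0), simp, P3)

    def test_unlifted_taxon_propagates_lookup_error(self, simp):
        with pytest.raises(UnknownTaxonError):
            decide_read(votes(99999, 0, 0), simp, P3)

    @given(st.data())
    def test_vote_permutation_invariance(self, simp, data):
        options = [0] + sorted(simp.parent)
        taxa = data.draw(st.lists(st.sampled_from(options), min_size=3, max_size=3))
        perm = data.draw(st.permutations(taxa))
        d1 = decide_read(votes(*taxa), simp, P3)
        d2 = decide_read(votes(*perm), simp, P3)
        assert (d1.taxon, d1.n_support, d1.score) == (d2.taxon, d2.n_support, d2.score)

    @given(st.data())
    def test_score_bound_and_threshold(self, simp, data):
        options = [0] + sorted(simp.parent)
        taxa = data.draw(st.lists(st.sampled_from(options), min_size=5, max_size=5))
        d = decide_read(ReadVotes("r", tuple(taxa)), simp, VotingParams(5))
        c, a, n = d.n_classified, d.n_support, 5
        if c >= 1:
            assert Fraction(a - 1, n) < d.score <= Fraction(a, n)
            assert (d.score == Fraction(a, n)) == (a == c)
            assert a > c // 2


class TestDecideAll:
    def test_empty_table(self, simp):
        assert decide_all([], simp, P3) == []

    def test_row_count_and_order(self, simp):
        sp = tv.species_nodes(simp)
        table = [votes(sp[i % len(sp)], 0, 0, read_id=f"r{i}") for i in range(7)]
        out = decide_all(table, simp, P3)
        assert [d.read_id for d in out] == [f"r{i}" for i in range(7)]

    def test_row_permutation_permutes_output(self, simp):
        sp = tv.species_nodes(simp)
        table = [votes(sp[i], sp[i], 0, read_id=f"r{i}") for i in range(4)]
        fwd = decide_all(table, simp, P3)
        rev = decide_all(table[::-1], simp, P3)
        assert rev == fwd[::-1]

    def test_error_carries_read_id(self, simp):
        with pytest.raises(TaxovoteError, match="rbad"):
            decide_all([votes(99999, 0, 0, read_id="rbad")], simp, P3)


class TestMinSupport:
    def test_min_support_one_is_identity(self, simp):
        sp = tv.species_nodes(simp)[0]
        d = decide_all([votes(sp, sp, 0)], simp, P3)
        assert apply_min_support(d, 1) == d

    def test_below_threshold_suppressed_with_audit(self, simp):
        sp = tv.species_nodes(simp)[0]
        [d] = decide_all([votes(sp, 0, 0)], simp, P3)
        [s] = apply_min_support([d], 3)
        assert s.taxon == 0 and s.below_min_support
        assert s.n_support == d.n_support and s.score == d.score

    def test_min_support_n_keeps_only_unanimous(self, simp):
        sp = tv.species_nodes(simp)
        table = [
            votes(sp[0], sp[0], sp[0], read_id="u"),
            votes(sp[0], sp[0], sp[1], read_id="m"),
            votes(0, 0, 0, read_id="z"),
        ]
        out = apply_min_support(decide_all(table, simp, P3), 3)
        by_id = {d.read_id: d for d in out}
        assert by_id["u"].taxon == sp[0]
        assert by_id["m"].taxon == 0 and by_id["m"].below_min_support
        assert by_id["z"].taxon == 0 and not by_id["z"].below_min_support

    def test_min_support_validates(self, simp):
        with pytest.raises(ValueError):
            apply_min_support([], 0)
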