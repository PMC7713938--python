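import itertools

import numpy as np
import pytest

from conftest import abstract_order
from mitokit.genome import ParseError
from mitokit.rearrangement import (GeneOrder, TdrlEvent, Token, apply_tdrl,
                                   breakpoint_distance, classify_type,
                                   diff_orders, order_from_genome,
                                   parse_gene_order, reference_order,
                                   tdrl_search)


class TestParse:
    def test_duplicate_cr_gets_distinct_indices(self):
        o = parse_gene_order("ND6-trnE-Cytb-CR-trnL2-ND5-CR")
        assert len(o) == 7
        crs = [t for t in o.tokens if t.name == "CR"]
        assert [t.dup_index for t in crs] == [0, 1]

    def test_dloop_synonym_in_dash_dialect(self):
        o = parse_gene_order("ND6-trnE-Cytb-D-loop-trnL2 (CUN)-ND5-D-loop")
        assert [t.name for t in o.tokens] == \
            ["ND6", "trnE", "Cytb", "CR", "trnL2", "ND5", "CR"]

    def test_pseudogene_and_shorthand(self):
        o = parse_gene_order("psH-S1-ND5")
        assert [t.name for t in o.tokens] == ["trnH", "trnS1", "ND5"]
        assert o.tokens[0].pseudo and not o.tokens[1].pseudo

    def test_strand_prefix(self):
        o = parse_gene_order("trnW -trnA -OL COI")
        assert [t.strand for t in o.tokens] == ["+", "-", "-", "+"]

    def test_empty_and_unknown_token_rejected(self):
        with pytest.raises(ParseError):
            parse_gene_order("")
        with pytest.raises(ParseError, match="NOTAGENE"):
            parse_gene_order("trnF NOTAGENE")


class TestOrderFromGenome:
    def test_published_order(self, omeimontis):
        o = order_from_genome(omeimontis)
        names = [t.name for t in o.tokens]
        assert names[:5] == ["trnL2", "trnT", "trnP", "trnF", "12S"]
        assert names[-4:] == ["ND6", "trnE", "Cytb", "CR"]
        i = names.index("OL")
        assert (names[i - 1], names[i + 1]) == ("trnN", "trnC")
        assert o.tokens[names.index("ND6")].strand == "-"

    def test_matches_shipped_reference(self, omeimontis):
        obs = order_from_genome(omeimontis)
        assert breakpoint_distance(reference_order(), obs) == 0

    def test_single_feature_genome(self):
        from mitokit.genome import CircularGenome, Feature
        g = CircularGenome("g", 100, features=[Feature("CR", "CR", 1, 100, "H")])
        assert [t.name for t in order_from_genome(g).tokens] == ["CR"]


class TestBreakpointDistance:
    def test_identity_and_rotation(self):
        a = abstract_order("A B C D")
        assert breakpoint_distance(a, a) == 0
        assert breakpoint_distance(a, a.rotated(2)) == 0

    def test_adjacent_swap(self):
        # circles ABCD / ACBD share only the D->A adjacency
        a = abstract_order("A B C D")
        b = abstract_order("A C B D")
        assert breakpoint_distance(a, b) == 3

    def test_strand_is_part_of_identity(self):
        a = abstract_order("A B C")
        b = abstract_order("A -B C")
        # rotation-equality respects strand; a strand-flipped copy is a
        # different token, so it is dropped as private before comparison
        assert a != b
        assert breakpoint_distance(a, b) == 0

    def test_private_tokens_dropped(self):
        # D is private to a; after dropping it the two circles agree
        a = abstract_order("A B C D")
        b = abstract_order("A B C")
        assert breakpoint_distance(a, b) == 0

    def test_pseudometric_on_random_triples(self, rng):
        tokens = list("ABCDEFG")
        for _ in range(25):
            orders = []
            for _ in range(3):
                perm = list(rng.permutation(tokens))
                orders.append(abstract_order(" ".join(perm)))
            x, y, z = orders
            dxy = breakpoint_distance(x, y)
            assert dxy == breakpoint_distance(y, x)
            assert dxy <= breakpoint_distance(x, z) + breakpoint_distance(z, y)
            assert breakpoint_distance(x, x) == 0


class TestDiffOrders:
    def test_ol_translocation_in_wancy(self):
        ref = abstract_order("W A OL N C Y")
        obs = abstract_order("W OL A N C Y")
        assert diff_orders(ref, obs).translocated == ["OL"]

    def test_gene_loss(self):
        ref = reference_order()
        obs = GeneOrder(tuple(t for t in ref.tokens
                              if t.name not in ("trnP", "trnF")))
        rep = diff_orders(ref, obs)
        assert rep.lost == ["trnF", "trnP"]
        assert rep.translocated == []

    def test_identical_orders_give_empty_report(self):
        ref = reference_order()
        rep = diff_orders(ref, ref.rotated(11))
        assert (rep.breakpoint_distance, rep.lost, rep.translocated,
                rep.duplicated, rep.pseudogenized) == (0, [], [], [], [])
        assert rep.type_label == "neobatrachian"

    def test_duplicated_and_pseudogenized(self):
        ref = abstract_order("A B CR")
        obs = abstract_order("A psB CR B CR")
        rep = diff_orders(ref, obs)
        assert rep.duplicated == ["CR"]
        assert rep.pseudogenized == ["B"]

    def test_planted_translocation_recovered(self, rng):
        tokens = list("ABCDEFGH")
        done = 0
        while done < 10:
            perm = list(rng.permutation(tokens))
            ref = abstract_order(" ".join(perm))
            moved = perm[2]
            old_neighbors = {perm[1], perm[3]}
            rest = [t for t in perm if t != moved]
            pos = int(rng.integers(0, len(rest)))
            cand = rest[:pos] + [moved] + rest[pos:]
            i = cand.index(moved)
            new_neighbors = {cand[i - 1], cand[(i + 1) % len(cand)]}
            # an adjacent exchange is explainable by either partner; only a
            # genuine jump has a unique single-token explanation
            if new_neighbors & old_neighbors:
                continue
            obs = abstract_order(" ".join(cand))
            assert diff_orders(ref, obs).translocated == [moved]
            done += 1


class TestClassifyType:
    def test_reference_is_neobatrachian_and_rotation_stable(self):
        ref = reference_order()
        assert classify_type(ref) == "neobatrachian"
        assert classify_type(ref.rotated(17)) == "neobatrachian"

    def _mutated_reference(self, drop=(), pseudo=()):
        toks = []
        for t in reference_order().tokens:
            if t.name in drop:
                continue
            if t.name in pseudo:
                t = Token(t.name, t.strand, True)
            toks.append(t)
        return GeneOrder(tuple(toks))

    def test_type_ix_loss_of_trnp_trnf(self):
        assert classify_type(self._mutated_reference(
            drop=("trnP", "trnF"))) == "IX"

    def test_type_ii_pseudo_s2(self):
        assert classify_type(self._mutated_reference(
            pseudo=("trnS2",))) == "II"

    def test_type_x_core_segment(self):
        o = parse_gene_order("trnS1 ND6 trnE Cytb CR trnL2 ND5 CR trnT")
        assert classify_type(o) == "X"

    def test_type_iii_ol_between_w_and_a(self):
        o = parse_gene_order("trnW OL trnA trnN trnC trnY")
        assert classify_type(o) == "III"

    def test_unknown_for_unclassified(self):
        assert classify_type(abstract_order("A B C")) == "unknown"


class TestApplyTdrl:
    def test_whole_order_keep_first_is_identity(self):
        o = abstract_order("A B C D")
        e = TdrlEvent(0, 4, ("first",) * 4)
        assert apply_tdrl(o, e) == o

    def test_single_gene_block_keep_second_is_identity(self):
        o = abstract_order("A B C")
        for start in range(3):
            e = TdrlEvent(start, 1, ("second",))
            assert apply_tdrl(o, e) == o

    def test_duplicate_cr_segment(self):
        # the duplicated-CR rearrangement: block ND5..trnL2 duplicated,
        # ND5 survives in the second copy, both CR copies retained
        src = parse_gene_order("ND5 -ND6 -trnE Cytb CR trnL2")
        e = TdrlEvent(0, 6, ("second", "first", "first", "first",
                             "both", "first"))
        out = apply_tdrl(src, e)
        assert out == parse_gene_order("-ND6 -trnE Cytb CR trnL2 ND5 CR")

    def test_both_restricted_to_cr_class(self):
        o = abstract_order("A CR")
        with pytest.raises(ValueError):
            apply_tdrl(o, TdrlEvent(0, 2, ("both", "first")))
        assert apply_tdrl(o, TdrlEvent(0, 2, ("first", "both"))) is not None


class TestTdrlSearch:
    def test_source_equals_target_gives_empty_scenario(self):
        o = abstract_order("A B C")
        assert tdrl_search(o, o) == [[]]

    def test_strand_preserving_reversal_unreachable(self):
        src = abstract_order("A B C D")
        tgt = abstract_order("A D C B")
        assert tdrl_search(src, tgt) == []

    def test_all_scenarios_produce_the_target(self):
        src = parse_gene_order("ND5 -ND6 -trnE Cytb CR trnL2")
        tgt = parse_gene_order("-ND6 -trnE Cytb CR trnL2 ND5 CR")
        scenarios = tdrl_search(src, tgt)
        assert scenarios
        for (e,) in scenarios:
            assert apply_tdrl(src, e) == tgt

    def test_full_genome_type_x_single_event(self):
        """One TDRL turns the reference order into the duplicated-CR type;
        some returned event must span the ND5..trnL2 block."""
        ref = reference_order()
        names = [t.name for t in ref.tokens]
        i = names.index("ND5")
        length = (names.index("trnL2") - i) % len(names) + 1
        rot = ref.tokens[i:] + ref.tokens[:i]
        kept = tuple("second" if t.name == "ND5" else
                     ("both" if t.name == "CR" else "first")
                     for t in rot[:length])
        target = apply_tdrl(ref, TdrlEvent(i, length, kept))
        assert classify_type(target) == "X"
        scenarios = tdrl_search(ref, target)
        assert scenarios
        assert all(apply_tdrl(ref, e) == target for (e,) in scenarios)
        blocks = {frozenset(names[(e.block_start + k) % len(names)]
                            for k in range(e.block_length))
                  for (e,) in scenarios}
        assert frozenset(
            ["ND5", "ND6", "trnE", "Cytb", "CR", "trnL2"]) in blocks

    def test_sorted_shortest_block_first(self):
        src = parse_gene_order("ND5 -ND6 -trnE Cytb CR trnL2")
        tgt = parse_gene_order("-ND6 -trnE Cytb CR trnL2 ND5 CR")
        lengths = [e.block_length for (e,) in tdrl_search(src, tgt)]
        assert lengths == sorted(lengths)


class TestSoundnessCompleteness:
    """tdrl_search recovers every applied event (an event producing the same
    target is always found)."""

    def test_exhaustive_five_tokens(self):
        o = abstract_order("A B C D E")
        n = len(o.tokens)
        for start, length in itertools.product(range(n), range(1, n + 1)):
            for kept in itertools.product(("first", "second"), repeat=length):
                e = TdrlEvent(start, length, kept)
                target = apply_tdrl(o, e)
                scenarios = tdrl_search(o, target)
                assert scenarios, (start, length, kept)
                for sc in scenarios:
                    cur = o
                    for ev in sc:
                        cur = apply_tdrl(cur, ev)
                    assert cur == target

    def test_random_eight_tokens_with_cr(self, rng):
        tokens = ["A", "B", "C", "D", "E", "F", "G", "CR"]
        for trial in range(12):
            perm = list(rng.permutation(tokens))
            o = abstract_order(" ".join(perm))
            start = int(rng.integers(0, 8))
            length = int(rng.integers(1, 9))
            block = [(start + k) % 8 for k in range(length)]
            kept = tuple(
                "both" if perm[i] == "CR" and rng.random() < 0.5
                else ("first" if rng.random() < 0.5 else "second")
                for i in block)
            e = TdrlEvent(start, length, kept)
            target = apply_tdrl(o, e)
            scenarios = tdrl_search(o, target)
            assert scenarios
            for sc in scenarios:
                cur = o
                for ev in sc:
                    cur = apply_tdrl(cur, ev)
                assert cur == target

    def test_two_event_composition_found(self):
        o = abstract_order("A B C D")
        e1 = TdrlEvent(0, 2, ("second", "first"))    # swap A,B
        mid = apply_tdrl(o, e1)
        e2 = TdrlEvent(2, 2, ("second", "first"))
        target = apply_tdrl(mid, e2)
        if tdrl_search(o, target, max_events=1):
            pytest.skip("composition collapses to a single event here")
        scenarios = tdrl_search(o, target, max_events=2)
        assert scenarios
        for sc in scenarios:
            cur = o
            for ev in sc:
                cur = apply_tdrl(cur, ev)
            assert cur == target
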