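"""Multiway-tree expansion, PDI and the greedy screen."""

import pytest

from pmskit import (
    ConfigurationError,
    TreeLayer,
    TreeNode,
    exhaustive_screen,
    expand_layer,
    greedy_screen,
    is_pms,
    minimal_subset,
    pdi,
)
from pmskit.core import UnknownMarkerError

from conftest import make_matrix, random_instance
from pmskit import SearchBudget, enumerate_parent_pairs, offspring_sets, ParentPool


def _layer(*pair_sets):
    return TreeLayer([TreeNode(frozenset(s)) for s in pair_sets])


class TestExpandLayer:
    def test_disjoint_singletons_make_two_leaves(self):
        matrix = make_matrix({
            "p1": {"m": "A/A"}, "p2": {"m": "A/A"},
            "p3": {"m": "B/B"}, "p4": {"m": "B/B"},
        })
        pairs = [("p1", "p2"), ("p3", "p4")]
        sets = offspring_sets(matrix, pairs, ["m"])
        nxt = expand_layer(_layer(pairs), "m", sets)
        assert sorted(n.pair_set for n in nxt.nodes) == [
            frozenset({("p1", "p2")}), frozenset({("p3", "p4")})
        ]
        assert all(n.is_leaf for n in nxt.nodes)

    def test_uninformative_marker_reproduces_parent_node(self):
        matrix = make_matrix({
            "p1": {"m": "A/B"}, "p2": {"m": "A/B"},
            "p3": {"m": "A/B"}, "p4": {"m": "A/B"},
        })
        pairs = [("p1", "p2"), ("p3", "p4")]
        sets = offspring_sets(matrix, pairs, ["m"])
        nxt = expand_layer(_layer(pairs), "m", sets)
        assert [n.pair_set for n in nxt.nodes] == [frozenset(pairs)]

    def test_overlapping_sets_match_membership_enumeration(self):
        # Genotype-induced children: each observable genotype keeps the
        # pairs whose Mendelian set contains it.
        matrix = make_matrix({
            "p1": {"m": "A/A"}, "p2": {"m": "A/A"},   # pair1 -> {AA}
            "p3": {"m": "A/B"}, "p4": {"m": "A/A"},   # pair2 -> {AA, AB}
            "p5": {"m": "B/B"}, "p6": {"m": "A/B"},   # pair3 -> {AB, BB}
        })
        pairs = [("p1", "p2"), ("p3", "p4"), ("p5", "p6")]
        sets = offspring_sets(matrix, pairs, ["m"])
        nxt = expand_layer(_layer(pairs), "m", sets)
        got = {n.pair_set for n in nxt.nodes}
        assert got == {
            frozenset({pairs[0], pairs[1]}),  # genotype AA
            frozenset({pairs[1], pairs[2]}),  # genotype AB
            frozenset({pairs[2]}),            # genotype BB
        }

    def test_unknown_marker_rejected(self):
        matrix = make_matrix({"p1": {"m": "A/A"}, "p2": {"m": "B/B"},
                              "p3": {"m": "C/C"}, "p4": {"m": "D/D"}})
        pairs = [("p1", "p2"), ("p3", "p4")]
        sets = offspring_sets(matrix, pairs, ["m"])
        with pytest.raises(UnknownMarkerError):
            expand_layer(_layer(pairs), "zzz", sets)


class TestPdi:
    def test_fully_resolving_marker_scores_zero(self):
        matrix = make_matrix({
            "p1": {"m": "A/A"}, "p2": {"m": "A/A"},
            "p3": {"m": "B/B"}, "p4": {"m": "B/B"},
        })
        pairs = [("p1", "p2"), ("p3", "p4")]
        sets = offspring_sets(matrix, pairs, ["m"])
        v = pdi(_layer(pairs), "m", sets)
        assert v.pdi == 0.0 and v.mean == 0.0 and v.sd == 0.0

    def test_two_branch_nodes_of_size_two(self):
        # child branch nodes {2, 2}: mean 2, sd 0, PDI 2
        matrix = make_matrix({
            "p1": {"m": "A/A"}, "p2": {"m": "A/A"},
            "p3": {"m": "A/B"}, "p4": {"m": "A/A"},
            "p5": {"m": "B/B"}, "p6": {"m": "B/B"},
            "p7": {"m": "B/C"}, "p8": {"m": "B/B"},
        })
        pairs = [("p1", "p2"), ("p3", "p4"), ("p5", "p6"), ("p7", "p8")]
        sets = offspring_sets(matrix, pairs, ["m"])
        # genotype AA keeps pairs 1,2; BB keeps pairs 3,4; AB leaf; BC leaf
        v = pdi(_layer(pairs), "m", sets)
        assert abs(v.mean - 2.0) < 1e-12
        assert abs(v.sd) < 1e-12
        assert abs(v.pdi - 2.0) < 1e-12

    def test_leaves_excluded_single_branch_node(self):
        # children sizes {3, 1}: the leaf is excluded, PDI = 3
        matrix = make_matrix({
            "p1": {"m": "A/A"}, "p2": {"m": "A/A"},
            "p3": {"m": "A/B"}, "p4": {"m": "A/A"},
            "p5": {"m": "A/A"}, "p6": {"m": "A/B"},
            "p7": {"m": "B/B"}, "p8": {"m": "B/B"},
        })
        pairs = [("p1", "p2"), ("p3", "p4"), ("p5", "p6"), ("p7", "p8")]
        sets = offspring_sets(matrix, pairs, ["m"])
        # genotype AA keeps pairs 1,2,3; AB keeps 2,3 ... recompute below
        v = pdi(_layer(pairs), "m", sets)
        # mendelian sets: pair1 {AA}, pair2 {AA,AB}, pair3 {AA,AB}, pair4 {BB}
        # children: AA -> {1,2,3}; AB -> {2,3}; BB -> {4} (leaf, dropped)
        assert abs(v.mean - 2.5) < 1e-12 and abs(v.sd - 0.5) < 1e-12
        assert abs(v.pdi - 3.0) < 1e-12

    def test_duplicate_branch_nodes_counted_once(self):
        # two parent branch nodes that split into identical children
        matrix = make_matrix({
            "p1": {"m": "A/B"}, "p2": {"m": "A/B"},
            "p3": {"m": "A/B"}, "p4": {"m": "A/B"},
        })
        pairs = [("p1", "p2"), ("p1", "p3"), ("p1", "p4")]
        layer = _layer([pairs[0], pairs[1]], [pairs[0], pairs[1], pairs[2]])
        sets = offspring_sets(matrix, pairs, ["m"])
        # every pair has the same offspring set, so each node's only child
        # is itself; dedup keeps both distinct nodes, sizes {2, 3}
        v = pdi(layer, "m", sets)
        assert abs(v.mean - 2.5) < 1e-12 and abs(v.sd - 0.5) < 1e-12


class TestGreedyScreen:
    def test_single_resolving_marker(self, toy_solvable):
        _, _, panel, pairs, sets = toy_solvable
        result = greedy_screen(panel, pairs, sets)
        assert result.best.marker_ids == ("m2",)
        assert result.best.source == "greedy"

    def test_unsolvable_report_matches_exhaustive(self):
        matrix = make_matrix({
            "p1": {"m1": "A/B", "m2": "C/C"},
            "p2": {"m1": "A/B", "m2": "C/C"},
            "p3": {"m1": "A/A", "m2": "C/D"},
        })
        pool = ParentPool(("p1", "p2", "p3"))
        pairs = enumerate_parent_pairs(pool, "unknown")
        sets = offspring_sets(matrix, pairs, matrix.marker_ids)
        g = greedy_screen(list(matrix.marker_ids), pairs, sets)
        e = exhaustive_screen(list(matrix.marker_ids), pairs, sets)
        assert g.unsolvable and e.unsolvable
        assert g.indistinguishable_pairs == e.indistinguishable_pairs

    def test_empty_panel_rejected(self, toy_solvable):
        _, _, _, pairs, sets = toy_solvable
        with pytest.raises(ConfigurationError):
            greedy_screen([], pairs, sets)

    def test_sound_and_bounded_on_random_instances(self, rng):
        """Greedy output is a working PMS, at least as large as the
        exhaustive minimum, with evaluations <= |PMS| x panel size, and
        non-redundant after de-redundancy."""
        solved = 0
        for _ in range(120):
            matrix, markers, pairs, sets = random_instance(
                rng, n_parents=4, n_markers=int(rng.integers(3, 9)), max_alleles=8
            )
            g = greedy_screen(markers, pairs, sets)
            e = exhaustive_screen(markers, pairs, sets)
            assert g.unsolvable == e.unsolvable
            if g.unsolvable:
                continue
            solved += 1
            gm = list(g.best.marker_ids)
            assert is_pms(gm, pairs, sets)
            assert len(gm) >= len(e.best)
            assert g.stats["indicator_evaluations"] <= max(len(gm), 1) * len(markers)
            core = minimal_subset(gm, pairs, sets)
            # no proper subset of the de-redundant core works
            for i in range(len(core)):
                reduced = [m for m in core.marker_ids if m != core.marker_ids[i]]
                assert not reduced or not is_pms(reduced, pairs, sets)
        assert solved >= 30  # the ensemble must exercise the solvable path

    def test_selected_marker_pdi_zero_iff_terminal(self, toy_solvable):
        _, _, panel, pairs, sets = toy_solvable
        result = greedy_screen(panel, pairs, sets)
        assert result.stats["selection_log"][-1]["score"] == 0.0

    def test_pic_pe_indicators_need_matrix(self, toy_solvable):
        _, _, panel, pairs, sets = toy_solvable
        with pytest.raises(ConfigurationError):
            greedy_screen(panel, pairs, sets, indicator="pic")

    @pytest.mark.parametrize("indicator", ["pic", "pe"])
    def test_alternative_indicators_terminate_with_working_pms(
        self, toy_solvable, indicator
    ):
        _, matrix, panel, pairs, sets = toy_solvable
        result = greedy_screen(panel, pairs, sets, indicator=indicator,
                               matrix=matrix)
        assert not result.unsolvable
        assert is_pms(list(result.best.marker_ids), pairs, sets)

    def test_determinism_and_panel_order_ties(self, rng):
        matrix, markers, pairs, sets = random_instance(rng, 4, 6, 4)
        r1 = greedy_screen(markers, pairs, sets)
        r2 = greedy_screen(markers, pairs, sets)
        if not r1.unsolvable:
            assert r1.best.marker_ids == r2.best.marker_ids
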