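"""Orientation brute force, gadget derivation, instance construction, back-mapping."""

import random

import pytest

from netmpl.core import enumerate_switchings, find_galls, level
from netmpl.parsimony import NetworkScorer, network_score_shared
from netmpl.reduction import (
    GADGET_COLUMN_U,
    GADGET_COLUMN_V,
    UndirectedGraph,
    build_instance,
    cubic_fixtures,
    maxcut_bruteforce,
    msso_bruteforce,
    orientation_from_solution,
    remove_gaps,
    verify_reduction,
)


class TestOrientationBruteForce:
    def test_single_edge(self):
        g = UndirectedGraph(("a", "b"), (("a", "b"),))
        value, witness = msso_bruteforce(g)
        assert value == 2
        assert witness.sources_plus_sinks == 2

    def test_known_values(self, fixtures_cubic):
        assert msso_bruteforce(fixtures_cubic["K4"])[0] == 2
        assert msso_bruteforce(fixtures_cubic["K33"])[0] == 6
        assert maxcut_bruteforce(fixtures_cubic["K4"]) == 4
        assert maxcut_bruteforce(fixtures_cubic["K33"]) == 9

    def test_witness_attains_value(self, fixtures_cubic):
        for g in fixtures_cubic.values():
            value, witness = msso_bruteforce(g)
            assert witness.sources_plus_sinks == value

    def test_msso_maxcut_relation_on_cubic_graphs(self, fixtures_cubic):
        for name in ("K4", "K33", "prism"):
            g = fixtures_cubic[name]
            assert msso_bruteforce(g)[0] == maxcut_bruteforce(g) - len(g.vertices) // 2

    def test_size_caps(self, fixtures_cubic):
        with pytest.raises(ValueError):
            msso_bruteforce(fixtures_cubic["petersen"], max_edges=10)
        with pytest.raises(ValueError):
            maxcut_bruteforce(fixtures_cubic["petersen"], max_vertices=5)

    def test_fixture_inventory(self, fixtures_cubic):
        sizes = {
            "K4": (4, 6),
            "K33": (6, 9),
            "prism": (6, 9),
            "petersen": (10, 15),
        }
        for name, (nv, ne) in sizes.items():
            g = fixtures_cubic[name]
            assert (len(g.vertices), len(g.edges)) == (nv, ne)
            assert g.is_cubic

    def test_edgelist_parsing(self):
        g = UndirectedGraph.from_edgelist("a b\nb c\n# comment\nc a\n")
        assert len(g.edges) == 3


class TestGadget:
    def test_switching_scores(self, gadget):
        scores = sorted(e.score for e in gadget.table)
        assert scores == [4, 4, 5, 5]
        assert gadget.min_score == 4
        assert gadget.bad_score == 5

    def test_good_switchings_have_complementary_singleton_roots(self, gadget):
        roots = {
            (gadget.table[i].root_u, gadget.table[i].root_v) for i in gadget.good
        }
        assert roots == {
            (frozenset({"0"}), frozenset({"1"})),
            (frozenset({"1"}), frozenset({"0"})),
        }

    def test_bad_switchings_have_ambiguous_roots(self, gadget):
        for i, entry in enumerate(gadget.table):
            if i not in gadget.good:
                assert entry.root_u == frozenset({"0", "1"})

    def test_structure(self, gadget):
        net = gadget.network
        assert len(net.taxa) == 6
        assert net.n_reticulations == 2
        assert level(net) == 1
        assert all(len(g.outgoing_arcs) == 3 for g in find_galls(net))

    def test_table_invariant_under_state_flip(self, gadget):
        # flipping 0 <-> 1 in both columns permutes the two good switchings
        # but preserves the score multiset
        flip_u = {i + 1: 1 - int(s) for i, s in enumerate(GADGET_COLUMN_U)}
        flip_v = {i + 1: 1 - int(s) for i, s in enumerate(GADGET_COLUMN_V)}
        from netmpl.reduction import _displayed_term, _fitch_term

        import itertools

        scores = []
        for ch in itertools.product((0, 1), repeat=2):
            t = _displayed_term(gadget.term, ch)
            scores.append(_fitch_term(t, flip_u)[1] + _fitch_term(t, flip_v)[1])
        assert sorted(scores) == [4, 4, 5, 5]


class TestInstance:
    def test_k4_instance_dimensions(self, k4_instance):
        inst = k4_instance
        assert len(inst.network.taxa) == 36
        assert inst.network.n_reticulations == 12
        assert inst.alignment.m == 4
        assert inst.gap_count == 72

    def test_k4_instance_is_level_one_with_three_arc_galls(self, k4_instance):
        net = k4_instance.network
        assert level(net) == 1
        galls = find_galls(net)
        assert len(galls) == 12
        assert all(len(g.outgoing_arcs) == 3 for g in galls)

    def test_k33_instance_dimensions(self, fixtures_cubic):
        inst = build_instance(fixtures_cubic["K33"])
        assert len(inst.network.taxa) == 54
        assert inst.network.n_reticulations == 18
        assert inst.alignment.m == 6
        assert inst.gap_count == 216

    def test_non_cubic_rejected(self):
        square = UndirectedGraph.from_networkx(__import__("networkx").cycle_graph(4))
        with pytest.raises(ValueError):
            build_instance(square)

    def test_column_states_per_edge(self, k4_instance):
        inst = k4_instance
        cols = tuple(sorted(inst.graph.vertices, key=str))
        for e in inst.graph.edges:
            u, v = e
            for i in range(1, 7):
                row = inst.alignment.row_of(f"x_{e[0]}-{e[1]}_{i}")
                assert row[cols.index(u)] == GADGET_COLUMN_U[i - 1]
                assert row[cols.index(v)] == GADGET_COLUMN_V[i - 1]
                others = [row[j] for j, w in enumerate(cols) if w not in e]
                assert set(others) <= {"-"}


class TestGapRemoval:
    def test_preserves_level_and_gall_arity(self, k4_instance):
        net2, aln2, _ = remove_gaps(k4_instance.network, k4_instance.alignment)
        assert level(net2) == 1
        assert all(len(g.outgoing_arcs) == 3 for g in find_galls(net2))
        assert len(net2.taxa) == 72
        assert aln2.gap_count == 0


class TestBackMapping:
    def test_identity_on_normalized_switchings(self, k4_instance):
        inst = k4_instance
        sw, entries = next(inst.good_switchings())
        orient, p_prime, normalized = orientation_from_solution(inst, sw)
        assert normalized.choices == sw.choices

    def test_sources_sinks_score_identity(self, k4_instance):
        # for any switching, after normalization: s = 7|V| - p'
        inst = k4_instance
        nv = len(inst.graph.vertices)
        rng = random.Random(7)
        pool = list(enumerate_switchings(inst.network))
        for sw in rng.sample(pool, 12):
            orient, p_prime, _ = orientation_from_solution(inst, sw)
            assert orient.sources_plus_sinks == 7 * nv - p_prime

    def test_optimal_switching_yields_msso_orientation(self, k4_instance):
        inst = k4_instance
        msso, _ = msso_bruteforce(inst.graph)
        best = network_score_shared(inst.network, inst.alignment, cap=2 ** 12)
        orient, p_prime, _ = orientation_from_solution(inst, best.switching)
        assert p_prime == best.score
        assert orient.sources_plus_sinks == msso


class TestVerifyReduction:
    def test_k4_good_mode(self, fixtures_cubic):
        rep = verify_reduction(fixtures_cubic["K4"], mode="good")
        assert rep.ok
        assert rep.mp_score == 26
        assert rep.gapless_score == 98

    def test_prism_good_mode(self, fixtures_cubic):
        rep = verify_reduction(fixtures_cubic["prism"], mode="good", include_gapless=False)
        assert rep.ok
        nv = len(fixtures_cubic["prism"].vertices)
        assert rep.mp_score == 7 * nv - rep.msso

    def test_bad_mode_rejected(self, fixtures_cubic):
        with pytest.raises(ValueError):
            verify_reduction(fixtures_cubic["K4"], mode="heuristic")
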