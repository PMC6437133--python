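"""Two-state likelihood: composition law, pruning vs extension sum, ML=MP link."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from netmpl.core import (
    Alignment,
    enumerate_switchings,
    extract_displayed_tree,
    height,
    topology_key,
)
from netmpl.generate import GeneratorConfig, random_alignment, random_level1_network
from netmpl.io import read_enewick, read_newick_tree
from netmpl.likelihood import (
    compose_path,
    compose_probabilities,
    displayed_trees_with_probs,
    likelihood_log_bounds,
    ml_mp_threshold_log,
    ml_tree_search,
    parsimony_rate_profile,
    tree_log_likelihood,
    tree_log_likelihood_bruteforce,
    verify_ml_is_mp,
)
from netmpl.parsimony import tree_score

probs = st.floats(min_value=0.0, max_value=0.5, allow_nan=False)


class TestCompose:
    def test_worked_value(self):
        assert compose_probabilities(0.1, 0.2) == pytest.approx(0.26)

    @given(probs)
    def test_zero_is_identity(self, p):
        assert compose_probabilities(p, 0.0) == pytest.approx(p)

    @given(probs)
    def test_half_is_absorbing(self, p):
        assert compose_probabilities(p, 0.5) == pytest.approx(0.5)

    @given(probs, probs)
    def test_commutative_and_in_range(self, p, q):
        a = compose_probabilities(p, q)
        assert a == pytest.approx(compose_probabilities(q, p))
        assert 0.0 <= a <= 0.5 + 1e-12

    @given(probs, probs, probs)
    def test_associative(self, p, q, r):
        left = compose_probabilities(compose_probabilities(p, q), r)
        right = compose_probabilities(p, compose_probabilities(q, r))
        assert left == pytest.approx(right, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compose_probabilities(0.6, 0.1)


class TestTreeLikelihood:
    def test_cherry_same_states(self, cherry_tree):
        aln = Alignment(("x", "y"), ("0", "0"), frozenset("01"))
        ep = {e: 0.1 for e in cherry_tree.graph.edges()}
        ll = tree_log_likelihood_bruteforce(cherry_tree, aln, ep)
        assert math.exp(ll.value) == pytest.approx(0.5 * (0.81 + 0.01))

    def test_cherry_different_states(self, cherry_tree):
        aln = Alignment(("x", "y"), ("0", "1"), frozenset("01"))
        ep = {e: 0.1 for e in cherry_tree.graph.edges()}
        ll = tree_log_likelihood(cherry_tree, aln, ep)
        assert math.exp(ll.value) == pytest.approx(0.1 * 0.9)

    def test_no_mutation_constant_character_gives_root_prior(self):
        t = read_newick_tree("((a,b),c);")
        aln = Alignment(("a", "b", "c"), ("0", "0", "0"), frozenset("01"))
        ep = {e: 0.0 for e in t.graph.edges()}
        for fn in (tree_log_likelihood, tree_log_likelihood_bruteforce):
            assert math.exp(fn(t, aln, ep).value) == pytest.approx(0.5)

    def test_impossible_character_is_minus_infinity(self):
        t = read_newick_tree("((a,b),c);")
        aln = Alignment(("a", "b", "c"), ("0", "1", "0"), frozenset("01"))
        ep = {e: 0.0 for e in t.graph.edges()}
        assert tree_log_likelihood(t, aln, ep).value == -math.inf

    def test_gap_rejected(self, cherry_tree):
        aln = Alignment(("x", "y"), ("0", "-"), frozenset("01"))
        ep = {e: 0.1 for e in cherry_tree.graph.edges()}
        with pytest.raises(ValueError):
            tree_log_likelihood(cherry_tree, aln, ep)

    @pytest.mark.parametrize("seed", range(20))
    def test_pruning_matches_extension_sum(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 8)
        cfg = GeneratorConfig(
            seed=seed, n_taxa=n, n_reticulations=0, n_characters=rng.randint(1, 3)
        )
        tree = random_level1_network(cfg)
        aln = random_alignment(cfg, tree.taxa)
        ep = {e: rng.uniform(0.0, 0.5) for e in tree.graph.edges()}
        a = tree_log_likelihood(tree, aln, ep).value
        b = tree_log_likelihood_bruteforce(tree, aln, ep).value
        assert a == pytest.approx(b, rel=1e-10)

    def test_stable_for_tiny_probabilities(self, cherry_tree):
        aln = Alignment(("x", "y"), ("0", "1"), frozenset("01"))
        ep = {e: 1e-40 for e in cherry_tree.graph.edges()}
        ll = tree_log_likelihood(cherry_tree, aln, ep)
        # either root state needs one flip: L = (p(1-p) + (1-p)p) / 2 = p(1-p)
        assert ll.value == pytest.approx(math.log(1e-40), rel=1e-9)


def _image_likelihood(net, dt, aln):
    """Oracle: likelihood computed on the uncontracted image with original arc probs."""
    arcs = [a for path in dt.image.values() for a in path]
    children = {}
    for (u, v) in arcs:
        children.setdefault(u, []).append(v)
    root = dt.tree.root
    total = 0.0
    for j in range(aln.m):
        col = aln.column(j)

        def below(v, state):
            if v not in children:
                return 1.0 if int(col[net.leaf_label[v]]) == state else 0.0
            out = 1.0
            for w in children[v]:
                p = net.arc_prob[(v, w)]
                out *= (1 - p) * below(w, state) + p * below(w, 1 - state)
            return out

        total += math.log(0.5 * (below(root, 0) + below(root, 1)))
    return total


class TestDisplayedTreesWithProbs:
    def test_tree_input_is_itself(self):
        t = read_enewick("((a:0.1,b:0.2):0.05,c:0.3);")
        (dt,) = displayed_trees_with_probs(t)
        assert topology_key(dt.tree) == topology_key(t)
        assert dt.tree.edge_prob == t.arc_prob

    def test_two_independent_galls_give_four_entries(self, gadget):
        net = gadget.network.with_arc_probs(0.1)
        assert len(displayed_trees_with_probs(net)) == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_contracted_edges_obey_path_bounds(self, seed):
        cfg = GeneratorConfig(seed=seed, n_taxa=6, n_reticulations=2,
                              prob_range=(0.01, 0.49))
        net = random_level1_network(cfg)
        for dt in displayed_trees_with_probs(net):
            for e, path in dt.image.items():
                ps = [net.arc_prob[a] for a in path]
                pe = dt.tree.edge_prob[e]
                assert pe == pytest.approx(compose_path(ps))
                assert pe <= 0.5
                if len(ps) > 1:
                    assert max(ps) < pe < sum(ps)
                else:
                    assert pe == pytest.approx(ps[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_contraction_consistency(self, seed):
        cfg = GeneratorConfig(seed=seed, n_taxa=5, n_reticulations=2,
                              n_characters=2, prob_range=(0.05, 0.45))
        net = random_level1_network(cfg)
        aln = random_alignment(cfg, net.taxa)
        for dt in displayed_trees_with_probs(net):
            contracted = tree_log_likelihood(dt.tree, aln).value
            assert contracted == pytest.approx(
                _image_likelihood(net, dt, aln), rel=1e-10
            )


class TestMLSearch:
    def test_tree_input_returns_own_likelihood(self):
        t = read_enewick("((a:0.1,b:0.2):0.05,c:0.3);")
        aln = Alignment(("a", "b", "c"), ("0", "1", "0"), frozenset("01"))
        res = ml_tree_search(t, aln)
        assert res.loglik.value == pytest.approx(
            tree_log_likelihood(t, aln).value
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_argmax_over_explicit_displayed_trees(self, seed):
        cfg = GeneratorConfig(seed=seed, n_taxa=6, n_reticulations=2,
                              n_characters=2, prob_range=(0.05, 0.45))
        net = random_level1_network(cfg)
        aln = random_alignment(cfg, net.taxa)
        res = ml_tree_search(net, aln)
        explicit = max(
            tree_log_likelihood(dt.tree, aln).value
            for dt in displayed_trees_with_probs(net)
        )
        assert res.loglik.value == pytest.approx(explicit)


class TestParsimonyLink:
    def test_threshold_arithmetic(self, gadget):
        # a network of height d with m characters and n taxa: d^(-2mn) 2^(-3mn)
        net = gadget.network
        d = height(net)
        got = ml_mp_threshold_log(net, m=2)
        assert got == pytest.approx(-24 * math.log(d) - 36 * math.log(2))
        assert ml_mp_threshold_log(net, m=0) == 0.0

    def test_threshold_monotone(self, gadget):
        net = gadget.network
        assert ml_mp_threshold_log(net, m=2) < ml_mp_threshold_log(net, m=1)
        assert ml_mp_threshold_log(net, m=1, n=8) < ml_mp_threshold_log(net, m=1, n=6)

    def test_bounds_ordered_and_scale_with_score(self):
        lo1, hi1 = likelihood_log_bounds(0.01, 3, m=2, n=6, net_height=5)
        assert lo1 < hi1
        lo2, hi2 = likelihood_log_bounds(0.01, 5, m=2, n=6, net_height=5)
        delta = 2 * math.log(0.01)
        assert lo2 == pytest.approx(lo1 + delta)
        assert hi2 == pytest.approx(hi1 + delta)

    def test_refuses_c_at_or_above_threshold(self, single_gall_net):
        aln = Alignment(("a", "b", "c"), ("0", "1", "0"), frozenset("01"))
        with pytest.raises(ValueError):
            verify_ml_is_mp(single_gall_net, aln, c=0.4)

    def test_tree_input_trivially_holds(self):
        t = read_newick_tree("((a,b),c);")
        aln = Alignment(("a", "b", "c"), ("0", "1", "0"), frozenset("01"))
        assert verify_ml_is_mp(t, aln).ok

    def test_lower_parsimony_wins_at_small_scale(self, gadget):
        # two displayed trees with different parsimony scores (the gadget's
        # optimal and suboptimal switchings): below some c* the more
        # parsimonious one has the higher likelihood at scale c
        rows = {
            str(i + 1): u + v
            for i, (u, v) in enumerate(zip("110001", "011100"))
        }
        aln = Alignment.from_rows(rows, alphabet={"0", "1"})
        all_dt = [
            extract_displayed_tree(gadget.network, s).tree
            for s in enumerate_switchings(gadget.network)
        ]
        by_score = sorted(all_dt, key=lambda t: tree_score(t, aln))
        trees = [by_score[0], by_score[-1]]
        scores = [tree_score(t, aln) for t in trees]
        assert scores[0] != scores[1]
        lo, hi = 0, 1
        rng = random.Random(0)
        p = [{e: rng.uniform(0.1, 0.5) for e in t.graph.edges()} for t in trees]
        crossed = None
        for k in range(1, 13):
            c = 10.0 ** -k
            lls = [
                tree_log_likelihood(trees[i], aln, {e: c * q for e, q in p[i].items()}).value
                for i in range(2)
            ]
            if crossed is None and lls[lo] > lls[hi]:
                crossed = k
            if crossed is not None:
                assert lls[lo] > lls[hi]  # stays crossed below c*
        assert crossed is not None

    def test_rate_profile_stabilizes(self, single_gall_net):
        aln = Alignment(("a", "b", "c"), ("01", "10", "00"), frozenset("01"))
        (s0, _) = list(enumerate_switchings(single_gall_net))
        tree = extract_displayed_tree(single_gall_net, s0).tree
        ep = {e: 0.3 for e in tree.graph.edges()}
        cs = [10.0 ** -k for k in range(1, 13)]
        prof = parsimony_rate_profile(tree, aln, ep, cs)
        diffs = [abs(prof[i + 1] - prof[i]) for i in range(len(prof) - 1)]
        assert diffs[-1] < 1e-8
        assert all(diffs[i + 1] <= diffs[i] + 1e-12 for i in range(len(diffs) - 1))
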