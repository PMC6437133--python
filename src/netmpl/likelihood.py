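"""Two-state symmetric (Cavender-Farris) likelihood of displayed trees.

Each binary character evolves independently down a tree ``(T, p)``: the
root state is 0 or 1 with probability 1/2 each, and each edge ``e`` flips
the state with probability ``p_e <= 1/2``.  The likelihood of a character
is the sum over all extensions of the product of per-edge flip/copy
probabilities, times the 1/2 root prior; an alignment multiplies across
characters.  All likelihoods here are carried in natural-log space with
per-node rescaling, so change probabilities as small as 1e-40 are handled
without underflow, and impossible outcomes give -inf exactly.

A network whose arcs carry change probabilities displays *trees with
probabilities*: suppressing an indegree-1/outdegree-1 node composes the
two arc probabilities as ``p = p1 (1 - p2) + (1 - p1) p2``, the flip
probability of a two-arc path.  A most likely (ML) displayed tree
maximizes the alignment likelihood over all switchings; distinct
switchings with equal topology but different composed probabilities are
kept as distinct candidates.

The link to parsimony: as all probabilities are scaled toward zero, a
tree's likelihood vanishes at rate ``c**l`` where ``l`` is its parsimony
score, so below an explicit threshold on a constant ``c`` (in terms of the
network height and problem size) every ML displayed tree is also most
parsimonious.  :func:`verify_ml_is_mp` checks that property end to end.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import reduce
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import (
    GAP,
    Alignment,
    DisplayedTree,
    EnumerationCapError,
    PhyloNetwork,
    PhyloTree,
    Switching,
    enumerate_switchings,
    extract_displayed_tree,
)
from .parsimony import DEFAULT_CAP, network_score_shared, tree_score

__all__ = [
    "compose_probabilities",
    "compose_path",
    "LogLikelihood",
    "tree_log_likelihood_bruteforce",
    "tree_log_likelihood",
    "displayed_trees_with_probs",
    "MLResult",
    "ml_tree_search",
    "ml_mp_threshold_log",
    "likelihood_log_bounds",
    "MLMPReport",
    "verify_ml_is_mp",
    "parsimony_rate_profile",
]


def compose_probabilities(p1: float, p2: float) -> float:
    """Flip probability of a two-edge path: ``p1 (1-p2) + (1-p1) p2``.

    Commutative and associative on [0, 1/2], with identity 0 and absorbing
    element 1/2; never leaves [0, 1/2].
    """
    for p in (p1, p2):
        if not (0.0 <= p <= 0.5):
            raise ValueError(f"probability {p} outside [0, 1/2]")
    return p1 * (1.0 - p2) + (1.0 - p1) * p2


def compose_path(probs: Iterable[float]) -> float:
    """Fold :func:`compose_probabilities` over a path's probabilities."""
    return reduce(compose_probabilities, probs)


@dataclass(frozen=True)
class LogLikelihood:
    """A likelihood in natural-log space (may be -inf) with per-character terms."""

    value: float
    per_character: Tuple[float, ...]

    def __float__(self) -> float:
        return self.value

    @property
    def probability(self) -> float:
        return math.exp(self.value) if self.value > -math.inf else 0.0


def _binary_columns(tree: PhyloTree, aln: Alignment) -> List[Dict[object, int]]:
    if not aln.alphabet <= {"0", "1"}:
        raise ValueError("likelihood requires the binary alphabet {0, 1}")
    if tree.taxa != tuple(sorted(aln.taxa)):
        raise ValueError("tree and alignment taxa differ")
    cols = []
    for j in range(aln.m):
        col = aln.column(j)
        states = {}
        for v, t in tree.leaf_label.items():
            s = col[t]
            if s == GAP:
                raise ValueError("gap symbols are not supported by the likelihood model")
            states[v] = int(s)
        cols.append(states)
    return cols


def _edge_probs(tree: PhyloTree, edge_prob) -> Dict[Tuple[object, object], float]:
    if not tree.is_tree:
        raise ValueError("likelihood of a network is out of scope; pass a tree")
    probs = tree.arc_prob if edge_prob is None else dict(edge_prob)
    if probs is None:
        raise ValueError("tree has no edge probabilities")
    if set(probs) != set(tree.graph.edges()):
        raise ValueError("edge probabilities must cover exactly the tree's edges")
    for e, p in probs.items():
        if not (0.0 <= p <= 0.5):
            raise ValueError(f"edge {e} probability {p} outside [0, 1/2]")
    return probs


def tree_log_likelihood_bruteforce(
    tree: PhyloTree,
    aln: Alignment,
    edge_prob: Optional[Mapping] = None,
) -> LogLikelihood:
    """Exact likelihood by summing over all extensions of every character.

    Exponential in the internal node count; the independent reference for
    the pruning implementation on small trees.
    """
    probs = _edge_probs(tree, edge_prob)
    cols = _binary_columns(tree, aln)
    internal = [v for v in tree.canonical_order if not tree.is_leaf(v)]
    edges = list(tree.graph.edges())
    per_char = []
    for leaf_state in cols:
        total = 0.0
        for assignment in itertools.product((0, 1), repeat=len(internal)):
            state = dict(zip(internal, assignment))
            state.update(leaf_state)
            prob = 0.5
            for (u, v) in edges:
                p = probs[(u, v)]
                prob *= p if state[u] != state[v] else 1.0 - p
            total += prob
        per_char.append(math.log(total) if total > 0.0 else -math.inf)
    return LogLikelihood(sum(per_char), tuple(per_char))


def tree_log_likelihood(
    tree: PhyloTree,
    aln: Alignment,
    edge_prob: Optional[Mapping] = None,
) -> LogLikelihood:
    """Alignment log-likelihood by dynamic programming over the tree.

    One post-order pass per character with conditional likelihood pairs
    rescaled at every node; agrees with the extension-sum reference to
    ~1e-10 relative tolerance on its domain and tolerates probabilities
    down to 1e-40 (and exactly 0).
    """
    probs = _edge_probs(tree, edge_prob)
    cols = _binary_columns(tree, aln)
    order = [v for v in reversed(tree.canonical_order)]
    succ = {v: tuple(tree.graph.successors(v)) for v in tree.graph}
    per_char = []
    for leaf_state in cols:
        vals: Dict[object, Tuple[float, float]] = {}
        logscale = 0.0
        dead = False
        for v in order:
            if not succ[v]:
                s = leaf_state[v]
                vals[v] = (1.0, 0.0) if s == 0 else (0.0, 1.0)
                continue
            v0 = v1 = 1.0
            for w in succ[v]:
                p = probs[(v, w)]
                c0, c1 = vals[w]
                v0 *= (1.0 - p) * c0 + p * c1
                v1 *= p * c0 + (1.0 - p) * c1
            scale = v0 if v0 >= v1 else v1
            if scale == 0.0:
                dead = True
                break
            vals[v] = (v0 / scale, v1 / scale)
            logscale += math.log(scale)
        if dead:
            per_char.append(-math.inf)
            continue
        r0, r1 = vals[tree.root]
        per_char.append(math.log(0.5 * (r0 + r1)) + logscale)
    return LogLikelihood(sum(per_char), tuple(per_char))


# -- displayed trees with probabilities and ML search ------------------------


def displayed_trees_with_probs(
    net: PhyloNetwork,
    cap: int = DEFAULT_CAP,
) -> List[DisplayedTree]:
    """All displayed trees of a probability-decorated network, one per switching.

    The same topology may recur with different composed probabilities;
    entries are kept separate, in lexicographic switching order.
    """
    if net.arc_prob is None:
        raise ValueError("network has no arc probabilities")
    if 2 ** net.n_reticulations > cap:
        raise EnumerationCapError(f"2^{net.n_reticulations} switchings exceed cap {cap}")
    return [extract_displayed_tree(net, s) for s in enumerate_switchings(net)]


@dataclass(frozen=True)
class MLResult:
    """A certified most likely displayed tree."""

    loglik: LogLikelihood
    tree: DisplayedTree
    switching: Switching


def ml_tree_search(
    net: PhyloNetwork,
    aln: Alignment,
    cap: int = DEFAULT_CAP,
) -> MLResult:
    """Exact argmax of the alignment likelihood over all displayed trees.

    Ties broken by the lexicographically smallest switching.
    """
    best: Optional[MLResult] = None
    for dt in displayed_trees_with_probs(net, cap=cap):
        ll = tree_log_likelihood(dt.tree, aln)
        if best is None or ll.value > best.loglik.value:
            best = MLResult(ll, dt, dt.switching)
    assert best is not None
    return best


# -- the likelihood / parsimony link -----------------------------------------


def ml_mp_threshold_log(net: PhyloNetwork, m: int, n: Optional[int] = None) -> float:
    """Natural log of the bound ``d^(-2mn) * 2^(-3mn)`` on the constant c.

    Below this bound (with every arc assigned the same change probability
    c), any most likely displayed tree is also most parsimonious.  ``d`` is
    the network height, ``m`` the character count, ``n`` the taxon count
    (defaults to the network's).  Returns 0 (log 1) for m = 0.
    """
    from .core import height

    if n is None:
        n = len(net.taxa)
    d = height(net)
    return -2.0 * m * n * math.log(d) - 3.0 * m * n * math.log(2.0)


def likelihood_log_bounds(
    c: float,
    parsimony_score: int,
    m: int,
    n: int,
    net_height: int,
) -> Tuple[float, float]:
    """Log-space bracket on L_A(T, p) for a tree displayed by a constant-c network.

    ``2^(-2mn) c^l  <  L  <  2^(mn) d^(2mn) c^l`` for 0 < c < 1/2, where
    ``l`` is the tree's parsimony score and ``d`` the network height.
    """
    if not (0.0 < c < 0.5):
        raise ValueError("c must lie strictly between 0 and 1/2")
    base = parsimony_score * math.log(c)
    lower = -2.0 * m * n * math.log(2.0) + base
    upper = m * n * math.log(2.0) + 2.0 * m * n * math.log(net_height) + base
    return lower, upper


@dataclass(frozen=True)
class MLMPReport:
    """Outcome of the ML-implies-MP check on a constant-c network."""

    ok: bool
    c: float
    threshold: float
    mp_score: int
    ml_tree_parsimony: int
    ml_loglik: float
    margin: int  # ml_tree_parsimony - mp_score (0 when ok)


def verify_ml_is_mp(
    net: PhyloNetwork,
    aln: Alignment,
    c: Optional[float] = None,
    cap: int = DEFAULT_CAP,
) -> MLMPReport:
    """Check that the ML displayed tree of (N, c) attains the MP score.

    Every arc is assigned the same change probability ``c``; when ``c`` is
    omitted, half the threshold is used.  A ``c`` at or above the threshold
    is refused.
    """
    log_thr = ml_mp_threshold_log(net, aln.m)
    threshold = math.exp(log_thr)
    if c is None:
        c = 0.5 * threshold
    elif not (0.0 < c < threshold):
        raise ValueError(f"c = {c} is not strictly below the threshold {threshold}")
    if c <= 0.0:
        raise ValueError("threshold underflows double precision for this problem size")
    netc = net.with_arc_probs(c)
    ml = ml_tree_search(netc, aln, cap=cap)
    mp = network_score_shared(net, aln, cap=cap)
    ml_l = tree_score(ml.tree.tree, aln)
    return MLMPReport(
        ok=(ml_l == mp.score),
        c=c,
        threshold=threshold,
        mp_score=mp.score,
        ml_tree_parsimony=ml_l,
        ml_loglik=ml.loglik.value,
        margin=ml_l - mp.score,
    )


def parsimony_rate_profile(
    tree: PhyloTree,
    aln: Alignment,
    edge_prob: Mapping,
    c_values: Sequence[float],
) -> List[float]:
    """Diagnostic for the small-scale rate of the likelihood.

    Returns ``log L_A(T, c p) - l log c`` for each ``c``; as ``c`` shrinks
    this stabilizes to a finite constant, showing the likelihood vanishes
    at rate ``c**l`` with ``l`` the tree's parsimony score.
    """
    l = tree_score(tree, aln)
    out = []
    for c in c_values:
        scaled = {e: c * p for e, p in dict(edge_prob).items()}
        ll = tree_log_likelihood(tree, aln, edge_prob=scaled)
        out.append(ll.value - l * math.log(c))
    return out
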