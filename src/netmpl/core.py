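"""Core types for rooted binary phylogenetic networks, trees and alignments.

A rooted binary phylogenetic network on a taxon set X is a directed acyclic
graph with a unique root (indegree 0, outdegree 2), leaves (indegree 1,
outdegree 0) bijectively labelled by X, and all remaining nodes either tree
nodes (indegree 1, outdegree 2) or reticulation nodes (indegree 2,
outdegree 1).  Arcs may optionally carry a state-change probability
``p_e`` in [0, 1/2] (the symmetric two-state model's per-branch flip
probability).

The *level* of a network is the maximum number of reticulation nodes in a
biconnected component of its underlying undirected graph.  In a level-1
network every non-trivial biconnected component is a simple cycle with
exactly one reticulation -- a *gall*.

A *switching* keeps exactly one incoming arc per reticulation; cleaning up
the resulting subtree (pruning unlabelled hanging subtrees, suppressing
degree-two nodes and an outdegree-1 root) yields a *displayed tree*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Dict, Iterable, Iterator, Mapping, Optional, Tuple

import networkx as nx

GAP = "-"

__all__ = [
    "GAP",
    "NetworkStructureError",
    "EnumerationCapError",
    "PhyloNetwork",
    "PhyloTree",
    "Alignment",
    "Switching",
    "DisplayedTree",
    "Gall",
    "level",
    "find_galls",
    "height",
    "enumerate_switchings",
    "switching_from_kept",
    "extract_displayed_tree",
    "displays",
    "topology_key",
]


class NetworkStructureError(ValueError):
    """The graph violates the rooted-binary-network invariants."""


class EnumerationCapError(RuntimeError):
    """A switching enumeration would exceed the configured cap."""


def _compose_pair(p1: float, p2: float) -> float:
    # probability of differing endpoint states on a two-arc path
    return p1 * (1.0 - p2) + (1.0 - p1) * p2


class PhyloNetwork:
    """Rooted binary phylogenetic network.

    Parameters
    ----------
    graph:
        Directed acyclic graph of the network (any hashable node ids).
    leaf_label:
        Mapping from leaf node to taxon name; must be a bijection with the
        leaves of ``graph``.
    arc_prob:
        Optional mapping from arc ``(u, v)`` to its change probability in
        ``[0, 1/2]``.  Either every arc has a probability or none does.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        leaf_label: Mapping[object, str],
        arc_prob: Optional[Mapping[Tuple[object, object], float]] = None,
        validate: bool = True,
    ) -> None:
        self.graph = graph
        self.leaf_label: Dict[object, str] = dict(leaf_label)
        self.arc_prob: Optional[Dict[Tuple[object, object], float]] = (
            None if arc_prob is None else {(u, v): float(p) for (u, v), p in arc_prob.items()}
        )
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise NetworkStructureError("empty graph")
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkStructureError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        if g.out_degree(root) != 2:
            raise NetworkStructureError("root must have outdegree 2")
        leaves = {v for v in g if g.out_degree(v) == 0}
        for v in g:
            ind, outd = g.in_degree(v), g.out_degree(v)
            if v == root:
                continue
            if outd == 0:
                if ind != 1:
                    raise NetworkStructureError(f"leaf {v!r} must have indegree 1")
            elif (ind, outd) not in ((1, 2), (2, 1)):
                raise NetworkStructureError(
                    f"node {v!r} has (in, out) = ({ind}, {outd}); "
                    "expected tree node (1,2) or reticulation (2,1)"
                )
        if set(self.leaf_label) != leaves:
            raise NetworkStructureError("leaf labels must cover exactly the leaves")
        labels = list(self.leaf_label.values())
        if len(set(labels)) != len(labels):
            raise NetworkStructureError("duplicate taxon labels")
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkStructureError("graph contains a directed cycle")
        if self.arc_prob is not None:
            arcs = set(g.edges())
            if set(self.arc_prob) != arcs:
                raise NetworkStructureError(
                    "arc probabilities must be given for every arc or for none"
                )
            for a, p in self.arc_prob.items():
                if not (0.0 <= p <= 0.5):
                    raise NetworkStructureError(f"arc {a} probability {p} outside [0, 1/2]")

    # -- basic structure ----------------------------------------------------

    @cached_property
    def root(self):
        return next(v for v in self.graph if self.graph.in_degree(v) == 0)

    @cached_property
    def taxa(self) -> Tuple[str, ...]:
        return tuple(sorted(self.leaf_label.values()))

    @cached_property
    def node_of_taxon(self) -> Dict[str, object]:
        return {t: v for v, t in self.leaf_label.items()}

    def is_leaf(self, v) -> bool:
        return self.graph.out_degree(v) == 0

    def is_reticulation(self, v) -> bool:
        return self.graph.in_degree(v) == 2

    @property
    def is_tree(self) -> bool:
        return self.n_reticulations == 0

    @cached_property
    def n_reticulations(self) -> int:
        return sum(1 for v in self.graph if self.graph.in_degree(v) == 2)

    # -- canonical ordering -------------------------------------------------
    #
    # Deterministic iteration: DFS preorder from the root with children
    # ordered by the smallest taxon name among their descendants.

    @cached_property
    def _min_taxon(self) -> Dict[object, str]:
        out: Dict[object, str] = {}
        for v in reversed(list(nx.topological_sort(self.graph))):
            if self.is_leaf(v):
                out[v] = self.leaf_label[v]
            else:
                out[v] = min(out[w] for w in self.graph.successors(v))
        return out

    def children(self, v) -> Tuple[object, ...]:
        return tuple(sorted(self.graph.successors(v), key=lambda w: self._min_taxon[w]))

    def parents(self, v) -> Tuple[object, ...]:
        return tuple(sorted(self.graph.predecessors(v), key=lambda u: self.preorder_index[u]))

    @cached_property
    def canonical_order(self) -> Tuple[object, ...]:
        order = []
        seen = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            # a reticulation is emitted the first time it is reached
            seen.add(v)
            order.append(v)
            for w in reversed(self.children(v)):
                if w not in seen:
                    stack.append(w)
        return tuple(order)

    @cached_property
    def preorder_index(self) -> Dict[object, int]:
        return {v: i for i, v in enumerate(self.canonical_order)}

    @cached_property
    def reticulations(self) -> Tuple[object, ...]:
        return tuple(v for v in self.canonical_order if self.is_reticulation(v))

    # -- derived copies -----------------------------------------------------

    def with_arc_probs(self, prob) -> "PhyloNetwork":
        """Return a copy whose arcs all carry probabilities.

        ``prob`` is either a scalar (assigned to every arc) or a mapping
        arc -> probability.
        """
        if isinstance(prob, Mapping):
            ap = dict(prob)
        else:
            ap = {a: float(prob) for a in self.graph.edges()}
        cls = PhyloTree if self.is_tree else PhyloNetwork
        return cls(self.graph.copy(), dict(self.leaf_label), ap)


class PhyloTree(PhyloNetwork):
    """Rooted binary phylogenetic tree: a network without reticulations."""

    def _validate(self) -> None:
        super()._validate()
        if self.n_reticulations:
            raise NetworkStructureError("a tree may not contain reticulation nodes")

    @property
    def edge_prob(self) -> Optional[Dict[Tuple[object, object], float]]:
        return self.arc_prob

    @classmethod
    def from_network(cls, net: PhyloNetwork) -> "PhyloTree":
        if not net.is_tree:
            raise NetworkStructureError("network has reticulations; not a tree")
        return cls(net.graph, net.leaf_label, net.arc_prob)


# -- alignments -------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Taxa-by-columns matrix of single-character discrete states.

    ``rows[i]`` is the sequence of ``taxa[i]``; the gap symbol ``"-"`` is a
    wildcard for parsimony purposes and is never a member of the alphabet.
    """

    taxa: Tuple[str, ...]
    rows: Tuple[str, ...]
    alphabet: frozenset

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon name")
        if GAP in self.alphabet:
            raise ValueError("gap symbol may not be part of the alphabet")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged rows")
        ok = set(self.alphabet) | {GAP}
        for t, r in zip(self.taxa, self.rows):
            bad = set(r) - ok
            if bad:
                raise ValueError(f"row {t!r} contains symbols outside the alphabet: {sorted(bad)}")

    @classmethod
    def from_rows(cls, rows: Mapping[str, str], alphabet: Optional[Iterable[str]] = None) -> "Alignment":
        taxa = tuple(rows)
        seqs = tuple(rows[t] for t in taxa)
        if alphabet is None:
            alphabet = {c for s in seqs for c in s if c != GAP}
        return cls(taxa, seqs, frozenset(alphabet))

    @property
    def m(self) -> int:
        """Number of columns (characters)."""
        return len(self.rows[0]) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.taxa)

    def column(self, j: int) -> Dict[str, str]:
        return {t: r[j] for t, r in zip(self.taxa, self.rows)}

    def columns(self) -> Iterator[Dict[str, str]]:
        for j in range(self.m):
            yield self.column(j)

    def row_of(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    @property
    def gap_count(self) -> int:
        return sum(r.count(GAP) for r in self.rows)


# -- switchings and displayed trees -----------------------------------------


@dataclass(frozen=True, order=True)
class Switching:
    """A choice of one retained incoming arc per reticulation node.

    ``choices[i]`` indexes (0 or 1) into the canonically ordered incoming
    arcs of the i-th reticulation in canonical order; switchings compare
    lexicographically on this vector.
    """

    choices: Tuple[int, ...]
    reticulations: Tuple[object, ...] = field(compare=False, repr=False)
    kept: Tuple[Tuple[object, object], ...] = field(compare=False, repr=False)
    removed: Tuple[Tuple[object, object], ...] = field(compare=False, repr=False)

    @property
    def kept_arcs(self) -> Dict[object, Tuple[object, object]]:
        return dict(zip(self.reticulations, self.kept))

    @property
    def removed_arcs(self) -> frozenset:
        return frozenset(self.removed)


def _retic_in_arcs(net: PhyloNetwork, v) -> Tuple[Tuple[object, object], ...]:
    return tuple((u, v) for u in net.parents(v))


def enumerate_switchings(net: PhyloNetwork) -> Iterator[Switching]:
    """Yield all 2**r switchings in lexicographic canonical order."""
    retics = net.reticulations
    in_arcs = [_retic_in_arcs(net, v) for v in retics]
    for choices in itertools.product((0, 1), repeat=len(retics)):
        kept = tuple(in_arcs[i][c] for i, c in enumerate(choices))
        removed = tuple(in_arcs[i][1 - c] for i, c in enumerate(choices))
        yield Switching(choices, retics, kept, removed)


def switching_from_kept(net: PhyloNetwork, kept: Mapping[object, Tuple[object, object]]) -> Switching:
    """Build a Switching of ``net`` from a reticulation -> kept-arc mapping."""
    retics = net.reticulations
    if set(kept) != set(retics):
        raise ValueError("kept-arc mapping must cover exactly the reticulation set")
    choices = []
    kept_t = []
    removed = []
    for v in retics:
        arcs = _retic_in_arcs(net, v)
        arc = tuple(kept[v])
        if arc not in arcs:
            raise ValueError(f"{arc} is not an incoming arc of reticulation {v!r}")
        c = arcs.index(arc)
        choices.append(c)
        kept_t.append(arc)
        removed.append(arcs[1 - c])
    return Switching(tuple(choices), retics, tuple(kept_t), tuple(removed))


@dataclass(frozen=True)
class DisplayedTree:
    """A tree displayed by a network, with its image inside the network.

    ``image[(u, w)]`` is the sequence of network arcs that were contracted
    into the tree edge ``(u, w)``; images of distinct tree edges are
    disjoint.  When the network carries arc probabilities, the tree's
    ``edge_prob`` composes them along each image path.
    """

    tree: PhyloTree
    switching: Switching
    image: Mapping[Tuple[object, object], Tuple[Tuple[object, object], ...]]


def extract_displayed_tree(net: PhyloNetwork, switching: Switching) -> DisplayedTree:
    """Extract the tree displayed by ``net`` under ``switching``.

    Cleanup order: iteratively delete unlabelled outdegree-0 nodes, trim an
    outdegree-1 root chain, then suppress indegree-1/outdegree-1 nodes
    (composing arc probabilities along suppressed paths).
    """
    removed = switching.removed_arcs
    g = net.graph
    out_children: Dict[object, set] = {
        v: {w for w in g.successors(v) if (v, w) not in removed} for v in g
    }
    in_parents: Dict[object, set] = {v: set() for v in g}
    for v, ws in out_children.items():
        for w in ws:
            in_parents[w].add(v)

    labelled = set(net.leaf_label)
    alive = set(g.nodes())
    stack = [v for v in g if not out_children[v] and v not in labelled]
    while stack:
        v = stack.pop()
        if v not in alive:
            continue
        alive.discard(v)
        for u in in_parents[v]:
            out_children[u].discard(v)
            if not out_children[u] and u not in labelled and u in alive:
                stack.append(u)

    root = net.root
    while len(out_children[root]) == 1:
        (child,) = out_children[root]
        alive.discard(root)
        root = child

    # contract indegree-1/outdegree-1 chains below the (possibly new) root
    edges = []
    image: Dict[Tuple[object, object], Tuple[Tuple[object, object], ...]] = {}
    probs: Dict[Tuple[object, object], float] = {}
    stack = [root]
    while stack:
        u = stack.pop()
        for first in out_children[u]:
            arcs = [(u, first)]
            v = first
            while out_children[v] and len(out_children[v]) == 1:
                (w,) = out_children[v]
                arcs.append((v, w))
                v = w
            edges.append((u, v))
            image[(u, v)] = tuple(arcs)
            if net.arc_prob is not None:
                p = net.arc_prob[arcs[0]]
                for a in arcs[1:]:
                    p = _compose_pair(p, net.arc_prob[a])
                probs[(u, v)] = p
            if out_children[v]:
                stack.append(v)

    tg = nx.DiGraph()
    tg.add_node(root)
    tg.add_edges_from(edges)
    labels = {v: net.leaf_label[v] for v in tg if tg.out_degree(v) == 0}
    tree = PhyloTree(tg, labels, probs if net.arc_prob is not None else None)
    return DisplayedTree(tree=tree, switching=switching, image=image)


# -- topology comparison and display test ------------------------------------


def topology_key(tree: PhyloTree) -> str:
    """Canonical string form of a tree topology (sorted nested taxon lists)."""

    def key(v) -> str:
        if tree.is_leaf(v):
            return tree.leaf_label[v]
        return "(" + ",".join(sorted(key(w) for w in tree.graph.successors(v))) + ")"

    return key(tree.root)


def displays(net: PhyloNetwork, tree: PhyloTree, cap: int = 2 ** 20) -> bool:
    """True iff some switching of ``net`` yields the topology of ``tree``.

    Exhaustive over the at most 2**r switchings; intended for small r.
    """
    if net.taxa != tree.taxa:
        raise ValueError("network and tree must be on the same taxon set")
    if 2 ** net.n_reticulations > cap:
        raise EnumerationCapError(
            f"2^{net.n_reticulations} switchings exceed cap {cap}"
        )
    target = topology_key(tree)
    for s in enumerate_switchings(net):
        if topology_key(extract_displayed_tree(net, s).tree) == target:
            return True
    return False


# -- level, galls, height ----------------------------------------------------


@dataclass(frozen=True)
class Gall:
    """A non-trivial biconnected component of a level-1 network.

    A simple cycle in the underlying undirected graph containing exactly one
    reticulation; ``outgoing_arcs`` are the arcs whose tail (but not head)
    lies on the cycle.
    """

    nodes: frozenset
    reticulation: object
    outgoing_arcs: Tuple[Tuple[object, object], ...]


def _blocks_with_reticulations(net: PhyloNetwork):
    und = nx.Graph(net.graph.to_undirected())
    for block_edges in nx.biconnected_component_edges(und):
        block_edges = {frozenset(e) for e in block_edges}
        nodes = {v for e in block_edges for v in e}
        retics = [
            v
            for v in nodes
            if net.is_reticulation(v)
            and all(frozenset((u, v)) in block_edges for u in net.graph.predecessors(v))
        ]
        yield block_edges, nodes, retics


def level(net: PhyloNetwork) -> int:
    """Maximum number of reticulations in a biconnected component; 0 iff a tree."""
    best = 0
    for _, _, retics in _blocks_with_reticulations(net):
        best = max(best, len(retics))
    return best


def find_galls(net: PhyloNetwork) -> Tuple[Gall, ...]:
    """All galls of a level-1 network, in canonical order of their reticulations."""
    galls = []
    for block_edges, nodes, retics in _blocks_with_reticulations(net):
        if len(block_edges) <= 1:
            continue
        if len(retics) != 1:
            raise NetworkStructureError(
                f"biconnected component with {len(retics)} reticulations: network is not level-1"
            )
        deg = {v: 0 for v in nodes}
        for e in block_edges:
            for v in e:
                deg[v] += 1
        if any(d != 2 for d in deg.values()):
            raise NetworkStructureError("non-cycle biconnected component in a level-1 network")
        outgoing = tuple(
            sorted(
                (
                    (u, w)
                    for u in nodes
                    for w in net.graph.successors(u)
                    if w not in nodes
                ),
                key=lambda a: (net.preorder_index[a[0]], net.preorder_index[a[1]]),
            )
        )
        galls.append(Gall(frozenset(nodes), retics[0], outgoing))
    galls.sort(key=lambda g: net.preorder_index[g.reticulation])
    return tuple(galls)


def height(net: PhyloNetwork) -> int:
    """Maximum number of arcs on a directed path in the network."""
    return nx.dag_longest_path_length(net.graph)
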