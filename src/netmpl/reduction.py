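"""Hardness-reduction machinery: orientations, the edge gadget, instances.

The construction encodes MAX-SOURCE-SINKS-ORIENTATION (msso) -- given an
undirected cubic graph G, orient every edge so as to maximize the number
of sources plus sinks -- as softwired parsimony on a binary level-1
network.  Every edge e = {u, v} of G becomes a copy of a fixed 6-taxon
gadget network N_e with two galls hanging off a caterpillar spine, and two
informative alignment columns (u: 1,1,0,0,0,1 and v: 0,1,1,1,0,0 across
the gadget's six taxa, gaps elsewhere).  The gadget has four switchings;
the two cheapest (4 mutations each) force complementary singleton root
states 0/1 in columns u and v and thereby encode the two orientations of
e, while the other two switchings cost 5.  Summed over the instance,

    mp(N, A) = 6|V| + (|V| - msso(G)) = 7|V| - msso(G),

which :func:`verify_reduction` checks end to end by brute force.  Gap
symbols can be eliminated by splitting every taxon into a cherry (a gap
becomes the 0/1 cherry), shifting every displayed tree's score by exactly
the gap count k = 6|V|(|E|-3).

The gadget's internal wiring is not transcribed from a picture: it is
*derived* by exhaustively enumerating all rooted binary level-1 networks
on six labelled leaves with exactly two 4-node galls (grammar
``S ::= leaf | internal(S, S) | gall(A=S, B=S, C=S)``) and accepting the
first candidate whose four switchings show the behaviour above.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .core import (
    GAP,
    Alignment,
    PhyloNetwork,
    Switching,
    switching_from_kept,
)
from .parsimony import NetworkScorer, network_score_shared

__all__ = [
    "UndirectedGraph",
    "Orientation",
    "msso_bruteforce",
    "maxcut_bruteforce",
    "Gadget",
    "GadgetSwitching",
    "derive_gadget",
    "GADGET_COLUMN_U",
    "GADGET_COLUMN_V",
    "ReductionInstance",
    "build_instance",
    "remove_gaps",
    "orientation_from_solution",
    "ReductionReport",
    "verify_reduction",
    "cubic_fixtures",
]

# States of the gadget's six taxa in the two informative columns.
GADGET_COLUMN_U = "110001"
GADGET_COLUMN_V = "011100"


# -- undirected graphs and orientations --------------------------------------


@dataclass(frozen=True)
class UndirectedGraph:
    """A simple undirected graph; edges stored as sorted pairs."""

    vertices: Tuple
    edges: Tuple[Tuple, ...]

    def __post_init__(self):
        vs = set(self.vertices)
        if len(vs) != len(self.vertices):
            raise ValueError("duplicate vertices")
        seen = set()
        for (u, v) in self.edges:
            if u == v:
                raise ValueError("self-loop")
            if u not in vs or v not in vs:
                raise ValueError(f"edge ({u}, {v}) has an endpoint outside the vertex set")
            if (u, v) != tuple(sorted((u, v), key=str)):
                raise ValueError("edges must be sorted pairs")
            if (u, v) in seen:
                raise ValueError("parallel edge")
            seen.add((u, v))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "UndirectedGraph":
        vs = tuple(sorted(g.nodes(), key=str))
        es = tuple(sorted((tuple(sorted(e, key=str)) for e in g.edges()), key=str))
        return cls(vs, es)

    @classmethod
    def from_edgelist(cls, text: str) -> "UndirectedGraph":
        """Parse one whitespace-separated ``u v`` pair per line."""
        g = nx.Graph()
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"bad edge line: {ln!r}")
            g.add_edge(parts[0], parts[1])
        return cls.from_networkx(g)

    def degree(self, v) -> int:
        return sum(1 for e in self.edges if v in e)

    @property
    def is_cubic(self) -> bool:
        return all(self.degree(v) == 3 for v in self.vertices)


@dataclass(frozen=True)
class Orientation:
    """An orientation of an undirected graph: one directed arc per edge."""

    graph: UndirectedGraph
    arcs: Tuple[Tuple, ...]  # aligned with graph.edges; each (tail, head)

    def __post_init__(self):
        if len(self.arcs) != len(self.graph.edges):
            raise ValueError("one arc per edge required")
        for e, a in zip(self.graph.edges, self.arcs):
            if set(a) != set(e):
                raise ValueError(f"arc {a} does not orient edge {e}")

    def _degrees(self):
        outd = {v: 0 for v in self.graph.vertices}
        ind = {v: 0 for v in self.graph.vertices}
        for (t, h) in self.arcs:
            outd[t] += 1
            ind[h] += 1
        return outd, ind

    @property
    def sources(self) -> Tuple:
        outd, ind = self._degrees()
        return tuple(v for v in self.graph.vertices if outd[v] > 0 and ind[v] == 0)

    @property
    def sinks(self) -> Tuple:
        outd, ind = self._degrees()
        return tuple(v for v in self.graph.vertices if ind[v] > 0 and outd[v] == 0)

    @property
    def sources_plus_sinks(self) -> int:
        return len(self.sources) + len(self.sinks)


def msso_bruteforce(graph: UndirectedGraph, max_edges: int = 24) -> Tuple[int, Orientation]:
    """Exact msso by enumerating all 2^|E| orientations; returns a witness."""
    edges = graph.edges
    if len(edges) > max_edges:
        raise ValueError(f"too many edges for brute force ({len(edges)} > {max_edges})")
    vidx = {v: i for i, v in enumerate(graph.vertices)}
    deg = [graph.degree(v) for v in graph.vertices]
    best = -1
    best_bits = 0
    for bits in range(1 << len(edges)):
        outd = [0] * len(deg)
        for i, (u, v) in enumerate(edges):
            t = u if bits >> i & 1 else v
            outd[vidx[t]] += 1
        s = sum(1 for i, d in enumerate(deg) if d and (outd[i] == d or outd[i] == 0))
        if s > best:
            best, best_bits = s, bits
    arcs = tuple(
        (u, v) if best_bits >> i & 1 else (v, u) for i, (u, v) in enumerate(edges)
    )
    return best, Orientation(graph, arcs)


def maxcut_bruteforce(graph: UndirectedGraph, max_vertices: int = 20) -> int:
    """Exact maximum cut by enumerating bipartitions."""
    vs = graph.vertices
    if len(vs) > max_vertices:
        raise ValueError(f"too many vertices for brute force ({len(vs)} > {max_vertices})")
    vidx = {v: i for i, v in enumerate(vs)}
    best = 0
    for bits in range(1 << max(0, len(vs) - 1)):  # fix the last vertex's side
        cut = 0
        for (u, v) in graph.edges:
            if (bits >> vidx[u] & 1) != (bits >> vidx[v] & 1):
                cut += 1
        best = max(best, cut)
    return best


def cubic_fixtures() -> Dict[str, UndirectedGraph]:
    """Named cubic graphs used throughout the verification harness."""
    return {
        "K4": UndirectedGraph.from_networkx(nx.complete_graph(4)),
        "K33": UndirectedGraph.from_networkx(nx.complete_bipartite_graph(3, 3)),
        "prism": UndirectedGraph.from_networkx(nx.circular_ladder_graph(3)),
        "petersen": UndirectedGraph.from_networkx(nx.petersen_graph()),
    }


# -- gadget derivation --------------------------------------------------------
#
# Terms: ('L', taxon) | ('I', a, b) | ('G', a, b, c).  A gall term is the
# 4-node cycle  top -> s1, top -> s2, s1 -> ret, s2 -> ret  with outgoing
# arcs s1 -> A, s2 -> B, ret -> C.  Keeping the s1 -> ret arc displays
# ((A, C), B); keeping s2 -> ret displays (A, (B, C)).


def _bipartitions(items: Tuple) -> Iterator[Tuple[Tuple, Tuple]]:
    head, rest = items[0], items[1:]
    for k in range(len(rest) + 1):
        for combo in itertools.combinations(rest, k):
            left = (head,) + combo
            right = tuple(x for x in rest if x not in combo)
            if right:
                yield left, right


def _terms(leaves: Tuple[int, ...], galls: int) -> Iterator[tuple]:
    """All gadget-grammar terms on ``leaves`` using exactly ``galls`` galls."""
    if len(leaves) == 1:
        if galls == 0:
            yield ("L", leaves[0])
        return
    for left, right in _bipartitions(leaves):
        for g1 in range(galls + 1):
            for a in _terms(left, g1):
                for b in _terms(right, galls - g1):
                    yield ("I", a, b)
    if galls >= 1 and len(leaves) >= 3:
        for c_part in _c_parts(leaves):
            ab = tuple(x for x in leaves if x not in c_part)
            for pa, pb in _bipartitions(ab):
                for ga in range(galls):
                    for gb in range(galls - ga):
                        gc = galls - 1 - ga - gb
                        for a in _terms(pa, ga):
                            for b in _terms(pb, gb):
                                for c in _terms(c_part, gc):
                                    yield ("G", a, b, c)


def _c_parts(items: Tuple) -> Iterator[Tuple]:
    for k in range(1, len(items) - 1):
        yield from itertools.combinations(items, k)


def _displayed_term(term: tuple, choices: Sequence[int]) -> tuple:
    """Binary tree term displayed under per-gall choices (preorder indexed)."""
    idx = [0]

    def rec(t):
        if t[0] == "L":
            return t
        if t[0] == "I":
            return ("I", rec(t[1]), rec(t[2]))
        my = choices[idx[0]]
        idx[0] += 1
        a, b, c = rec(t[1]), rec(t[2]), rec(t[3])
        if my == 0:  # keep s1 -> ret: C joins A
            return ("I", ("I", a, c), b)
        return ("I", a, ("I", b, c))

    return rec(term)


def _fitch_term(tree: tuple, column: Mapping[int, int]) -> Tuple[int, int]:
    """(root mask, union count) of a binary term; masks: bit0 = state 0."""
    if tree[0] == "L":
        return 1 << column[tree[1]], 0
    ma, ua = _fitch_term(tree[1], column)
    mb, ub = _fitch_term(tree[2], column)
    inter = ma & mb
    if inter:
        return inter, ua + ub
    return ma | mb, ua + ub + 1


@dataclass(frozen=True)
class GadgetSwitching:
    """Behaviour of one gadget switching on the two informative columns."""

    choices: Tuple[int, int]  # per-gall kept side, galls in preorder
    score: int  # mutations = Fitch union events within the gadget subtree
    root_u: frozenset  # Fitch root state set in column u
    root_v: frozenset


@dataclass(frozen=True)
class Gadget:
    """The derived 6-taxon edge gadget with its full switching table."""

    term: tuple
    network: PhyloNetwork
    table: Tuple[GadgetSwitching, ...]
    good: Tuple[int, int]  # indices into table of the two optimal switchings
    gall_arcs: Tuple[Tuple[object, Tuple, Tuple], ...]  # (ret, keep-0 arc, keep-1 arc)

    @property
    def min_score(self) -> int:
        return self.table[self.good[0]].score

    @property
    def bad_score(self) -> int:
        return next(e.score for i, e in enumerate(self.table) if i not in self.good)

    def kept_arcs(self, choices: Sequence[int]) -> Dict[object, Tuple]:
        """Reticulation -> kept-arc mapping for per-gall choices."""
        return {
            ret: (a0 if ch == 0 else a1)
            for (ret, a0, a1), ch in zip(self.gall_arcs, choices)
        }


_STATE_SETS = {1: frozenset({"0"}), 2: frozenset({"1"}), 3: frozenset({"0", "1"})}


def _evaluate_term(term: tuple) -> Optional[Tuple[Tuple[GadgetSwitching, ...], Tuple[int, int]]]:
    col_u = {i + 1: int(s) for i, s in enumerate(GADGET_COLUMN_U)}
    col_v = {i + 1: int(s) for i, s in enumerate(GADGET_COLUMN_V)}
    table = []
    for ch in itertools.product((0, 1), repeat=2):
        t = _displayed_term(term, ch)
        mu, uu = _fitch_term(t, col_u)
        mv, uv = _fitch_term(t, col_v)
        table.append(
            GadgetSwitching(ch, uu + uv, _STATE_SETS[mu], _STATE_SETS[mv])
        )
    scores = [e.score for e in table]
    lo = min(scores)
    good = tuple(i for i, s in enumerate(scores) if s == lo)
    if len(good) != 2:
        return None
    bad = [s for s in scores if s != lo]
    if len(bad) != 2 or bad[0] != bad[1] or bad[0] <= lo:
        return None
    roots = {(table[i].root_u, table[i].root_v) for i in good}
    want = {
        (frozenset({"0"}), frozenset({"1"})),
        (frozenset({"1"}), frozenset({"0"})),
    }
    if roots != want:
        return None
    return tuple(table), good


def _term_to_network(term: tuple) -> Tuple[PhyloNetwork, Tuple]:
    g = nx.DiGraph()
    labels: Dict[int, str] = {}
    galls: List[Tuple] = []
    counter = itertools.count()

    def build(t) -> int:
        if t[0] == "L":
            v = next(counter)
            g.add_node(v)
            labels[v] = str(t[1])
            return v
        if t[0] == "I":
            v = next(counter)
            g.add_node(v)
            g.add_edge(v, build(t[1]))
            g.add_edge(v, build(t[2]))
            return v
        top, s1, s2, ret = (next(counter) for _ in range(4))
        slot = len(galls)
        galls.append(None)  # reserve preorder slot before recursing
        g.add_edges_from([(top, s1), (top, s2), (s1, ret), (s2, ret)])
        g.add_edge(s1, build(t[1]))
        g.add_edge(s2, build(t[2]))
        g.add_edge(ret, build(t[3]))
        galls[slot] = (ret, (s1, ret), (s2, ret))
        return top

    build(term)
    return PhyloNetwork(g, labels), tuple(galls)


@lru_cache(maxsize=1)
def derive_gadget() -> Gadget:
    """Derive the edge gadget by exhaustive search over the gall grammar.

    Enumerates, in a fixed deterministic order, every term on the leaves
    1..6 with exactly two galls; accepts a term iff, on the two informative
    columns, exactly two of its four switchings attain the minimum score,
    those two have complementary singleton root sets ({0},{1}) and
    ({1},{0}), and the other two share a strictly larger score.  The first
    accepted term is canonical.  Raises if the search exhausts.
    """
    for term in _terms(tuple(range(1, 7)), 2):
        hit = _evaluate_term(term)
        if hit is None:
            continue
        table, good = hit
        network, gall_arcs = _term_to_network(term)
        return Gadget(term, network, table, good, gall_arcs)
    raise RuntimeError("gadget search exhausted without an accepted candidate")


# -- instance construction ----------------------------------------------------


def _edge_name(e: Tuple) -> str:
    return f"{e[0]}-{e[1]}"


@dataclass(frozen=True)
class ReductionInstance:
    """A cubic graph together with its parsimony instance (N, A).

    ``gadget_galls[e]`` lists, per gall of edge e's gadget copy (preorder),
    the relabelled reticulation and its two keepable arcs, so switchings
    can be assembled per edge.
    """

    graph: UndirectedGraph
    network: PhyloNetwork
    alignment: Alignment
    gadget: Gadget
    gadget_roots: Mapping[Tuple, object]
    gadget_taxa: Mapping[Tuple, Tuple[str, ...]]
    gadget_galls: Mapping[Tuple, Tuple[Tuple[object, Tuple, Tuple], ...]]

    @property
    def gap_count(self) -> int:
        return self.alignment.gap_count

    def switching_for(self, entry_per_edge: Mapping[Tuple, int]) -> Switching:
        """Switching using the given gadget table entry for every edge."""
        kept = {}
        for e in self.graph.edges:
            entry = self.gadget.table[entry_per_edge[e]]
            for (ret, a0, a1), ch in zip(self.gadget_galls[e], entry.choices):
                kept[ret] = a0 if ch == 0 else a1
        return switching_from_kept(self.network, kept)

    def good_switchings(self) -> Iterator[Tuple[Switching, Dict[Tuple, int]]]:
        """All switchings in which every gadget uses one of its two optima."""
        edges = self.graph.edges
        for combo in itertools.product(self.gadget.good, repeat=len(edges)):
            entry_per_edge = dict(zip(edges, combo))
            yield self.switching_for(entry_per_edge), entry_per_edge


def build_instance(graph: UndirectedGraph) -> ReductionInstance:
    """Build the parsimony instance (N, A) encoding msso on a cubic graph.

    N replaces each taxon of a caterpillar on the (sorted) edge set with a
    copy of the derived gadget; A has one column per vertex, with edge
    e = {u, v}'s six taxa reading 1,1,0,0,0,1 at u, 0,1,1,1,0,0 at v and
    gaps elsewhere.
    """
    if not graph.is_cubic:
        raise ValueError("instance construction requires a cubic graph")
    if len(graph.edges) < 2:
        raise ValueError("need at least two edges")
    gadget = derive_gadget()

    g = nx.DiGraph()
    labels: Dict[object, str] = {}
    roots: Dict[Tuple, object] = {}
    taxa_of: Dict[Tuple, Tuple[str, ...]] = {}
    galls_of: Dict[Tuple, Tuple] = {}
    for e in graph.edges:
        tag = _edge_name(e)
        mapping = {v: (tag, v) for v in gadget.network.graph}
        for (u, v) in gadget.network.graph.edges():
            g.add_edge(mapping[u], mapping[v])
        taxa = []
        for node, taxon in gadget.network.leaf_label.items():
            name = f"x_{tag}_{taxon}"
            labels[mapping[node]] = name
            taxa.append(name)
        roots[e] = mapping[gadget.network.root]
        taxa_of[e] = tuple(sorted(taxa))
        galls_of[e] = tuple(
            (mapping[ret], (mapping[a0[0]], mapping[a0[1]]), (mapping[a1[0]], mapping[a1[1]]))
            for (ret, a0, a1) in gadget.gall_arcs
        )

    # left-deep caterpillar over the sorted edges; its one cherry holds the
    # first two gadgets
    spine_root = roots[graph.edges[0]]
    for i, e in enumerate(graph.edges[1:], start=1):
        join = ("spine", i)
        g.add_edge(join, spine_root)
        g.add_edge(join, roots[e])
        spine_root = join

    network = PhyloNetwork(g, labels)

    columns = tuple(sorted(graph.vertices, key=str))
    rows: Dict[str, str] = {}
    for e in graph.edges:
        u, v = e
        tag = _edge_name(e)
        for i in range(1, 7):
            row = []
            for w in columns:
                if w == u:
                    row.append(GADGET_COLUMN_U[i - 1])
                elif w == v:
                    row.append(GADGET_COLUMN_V[i - 1])
                else:
                    row.append(GAP)
            rows[f"x_{tag}_{i}"] = "".join(row)
    aln = Alignment(tuple(rows), tuple(rows.values()), frozenset({"0", "1"}))

    return ReductionInstance(graph, network, aln, gadget, roots, taxa_of, galls_of)


# -- gap removal --------------------------------------------------------------


def remove_gaps(net: PhyloNetwork, aln: Alignment):
    """Encode gaps away by splitting every taxon into a cherry.

    A taxon with state 0/1 becomes two leaves with that state; a gap
    becomes the 0/1 cherry, whose forced mutation makes the cherry's parent
    state irrelevant -- the wildcard, re-encoded.  Returns ``(N', A',
    g)`` where ``g`` maps a switching of N to the corresponding switching
    of N'; every displayed tree's score grows by exactly the gap count,
    and neither the level nor any gall's outgoing-arc count changes.
    """
    if not aln.alphabet <= {"0", "1"}:
        raise ValueError("gap removal is defined for alignments over {0, 1, -}")
    g2 = net.graph.copy()
    labels: Dict[object, str] = {}
    arc_prob = dict(net.arc_prob) if net.arc_prob is not None else None
    for leaf, taxon in net.leaf_label.items():
        c1, c2 = ("split", leaf, 1), ("split", leaf, 2)
        g2.add_edge(leaf, c1)
        g2.add_edge(leaf, c2)
        labels[c1] = f"{taxon}.1"
        labels[c2] = f"{taxon}.2"
        if arc_prob is not None:
            arc_prob[(leaf, c1)] = 0.0
            arc_prob[(leaf, c2)] = 0.0
    net2 = PhyloNetwork(g2, labels, arc_prob)

    taxa2: List[str] = []
    rows2: List[str] = []
    for t, r in zip(aln.taxa, aln.rows):
        taxa2 += [f"{t}.1", f"{t}.2"]
        rows2.append(r.replace(GAP, "0"))
        rows2.append(r.replace(GAP, "1"))
    aln2 = Alignment(tuple(taxa2), tuple(rows2), frozenset({"0", "1"}))

    def g(switching: Switching) -> Switching:
        return switching_from_kept(net2, switching.kept_arcs)

    return net2, aln2, g


# -- back-mapping and end-to-end verification ---------------------------------


def orientation_from_solution(
    inst: ReductionInstance, switching: Switching
) -> Tuple[Orientation, int, Switching]:
    """Back-map a switching of the instance to an orientation of the graph.

    First normalizes every gadget to one of its two optimal switchings,
    choosing per gadget the cheaper replacement (never increasing the total
    mutation count), then reads the orientation off the root states: state
    1 at an endpoint's column means the edge leaves that endpoint.  Returns
    the orientation, the normalized mutation count p', and the normalized
    switching.
    """
    scorer = NetworkScorer(inst.network, inst.alignment)
    gadget = inst.gadget
    kept = dict(switching.kept_arcs)

    def entry_of(e) -> int:
        choices = []
        for (ret, a0, a1) in inst.gadget_galls[e]:
            choices.append(0 if kept[ret] == a0 else 1)
        choices = tuple(choices)
        return next(i for i, t in enumerate(gadget.table) if t.choices == choices)

    def total() -> int:
        sw = switching_from_kept(inst.network, kept)
        return scorer.score(sw.removed_arcs)[0]

    entries: Dict[Tuple, int] = {}
    for e in inst.graph.edges:
        idx = entry_of(e)
        if idx in gadget.good:
            entries[e] = idx
            continue
        best: Optional[Tuple[int, int]] = None
        for gi in gadget.good:
            for (ret, a0, a1), ch in zip(inst.gadget_galls[e], gadget.table[gi].choices):
                kept[ret] = a0 if ch == 0 else a1
            sc = total()
            if best is None or sc < best[0]:
                best = (sc, gi)
        gi = best[1]
        for (ret, a0, a1), ch in zip(inst.gadget_galls[e], gadget.table[gi].choices):
            kept[ret] = a0 if ch == 0 else a1
        entries[e] = gi

    normalized = switching_from_kept(inst.network, kept)
    p_prime = scorer.score(normalized.removed_arcs)[0]

    arcs = []
    for e in inst.graph.edges:
        u, v = e
        entry = gadget.table[entries[e]]
        # root state 1 in a column marks the edge as outgoing at that vertex
        if entry.root_u == frozenset({"1"}):
            arcs.append((u, v))
        else:
            arcs.append((v, u))
    return Orientation(inst.graph, tuple(arcs)), p_prime, normalized


@dataclass(frozen=True)
class ReductionReport:
    """End-to-end check of the score identities on one cubic graph."""

    msso: int
    mp_score: int
    expected: int  # 6|V| + (|V| - msso)
    identity_ok: bool
    gap_count: int
    gapless_score: Optional[int]
    gapless_expected: Optional[int]
    gapless_ok: Optional[bool]
    mode: str
    n_switchings: int

    @property
    def ok(self) -> bool:
        return self.identity_ok and (self.gapless_ok is not False)


def verify_reduction(
    graph: UndirectedGraph,
    mode: str = "good",
    include_gapless: bool = True,
) -> ReductionReport:
    """Brute-force both sides of the score identities for a cubic graph.

    ``mode="full"`` enumerates all 4^|E| switchings of the instance;
    ``mode="good"`` only the 2^|E| switchings in which every gadget uses an
    optimal switching (lossless, since any other gadget switching can be
    replaced without increasing the score).
    """
    if mode not in ("full", "good"):
        raise ValueError("mode must be 'full' or 'good'")
    inst = build_instance(graph)
    msso, _ = msso_bruteforce(graph)
    nv = len(graph.vertices)
    expected = 6 * nv + (nv - msso)

    if mode == "full":
        result = network_score_shared(
            inst.network, inst.alignment, cap=2 ** (2 * len(graph.edges))
        )
        mp = result.score
        n_sw = 4 ** len(graph.edges)
        switchings = None
    else:
        scorer = NetworkScorer(inst.network, inst.alignment)
        switchings = [s for s, _ in inst.good_switchings()]
        mp = min(scorer.score(s.removed_arcs)[0] for s in switchings)
        n_sw = len(switchings)

    gapless_score = gapless_expected = gapless_ok = None
    if include_gapless:
        net2, aln2, g = remove_gaps(inst.network, inst.alignment)
        scorer2 = NetworkScorer(net2, aln2)
        if mode == "full":
            from .core import enumerate_switchings

            pool = (g(s) for s in enumerate_switchings(inst.network))
        else:
            pool = (g(s) for s in switchings)
        gapless_score = min(scorer2.score(s.removed_arcs)[0] for s in pool)
        gapless_expected = inst.gap_count + expected
        gapless_ok = gapless_score == gapless_expected

    return ReductionReport(
        msso=msso,
        mp_score=mp,
        expected=expected,
        identity_ok=(mp == expected and mp == 7 * nv - msso),
        gap_count=inst.gap_count,
        gapless_score=gapless_score,
        gapless_expected=gapless_expected,
        gapless_ok=gapless_ok,
        mode=mode,
        n_switchings=n_sw,
    )
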