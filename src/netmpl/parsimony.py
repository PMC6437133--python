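"""Small parsimony on trees and softwired parsimony on networks.

Column scores come from Fitch's algorithm: the bottom-up phase assigns each
node the intersection of its children's state sets when non-empty, else
their union; every union is one unavoidable mutation, so the union count is
the column's parsimony score.  A gap symbol is a wildcard: the leaf gets
the full alphabet and never forces a mutation.

A network's softwired score is minimized over the trees it displays.  Two
published definitions exist: the *shared-tree* score (one displayed tree
for the whole alignment, the definition adopted throughout this package)
and the *per-column* score (each character picks its own displayed tree);
the latter never exceeds the former.  Both are computed by exhaustive
switching enumeration -- the naive ``2^r`` strategy -- guarded by a cap.

Scoring a switching does not require building the displayed tree: Fitch's
state sets are invariant under suppressing degree-two nodes and pruning
unlabelled hanging subtrees, so one bottom-up pass over the switching
subtree of the network suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

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

__all__ = [
    "FitchAnnotation",
    "fitch_column",
    "fitch_extension",
    "tree_score",
    "MPResult",
    "network_score_shared",
    "network_score_percolumn",
    "NetworkScorer",
    "GapRemovalReport",
    "check_gap_removal",
]

DEFAULT_CAP = 2 ** 20


@dataclass(frozen=True)
class FitchAnnotation:
    """Bottom-up Fitch state sets for one column on one tree.

    ``union_count`` equals the column's parsimony score; ``sets`` maps every
    node to its (non-empty) state set, with gap leaves carrying the full
    alphabet.
    """

    tree: PhyloTree
    alphabet: Tuple[str, ...]
    sets: Mapping[object, frozenset]
    union_count: int
    root_set: frozenset


def _check_column(tree_taxa: Sequence[str], column: Mapping[str, str], alphabet) -> None:
    if not alphabet:
        raise ValueError("empty alphabet")
    missing = set(tree_taxa) - set(column)
    if missing:
        raise ValueError(f"column missing taxa: {sorted(missing)}")
    bad = {s for t, s in column.items() if s != GAP and s not in alphabet}
    if bad:
        raise ValueError(f"states outside alphabet: {sorted(bad)}")


def fitch_column(
    tree: PhyloTree,
    column: Mapping[str, str],
    alphabet: Optional[Iterable[str]] = None,
) -> FitchAnnotation:
    """Run the bottom-up Fitch phase for one character on a tree."""
    if alphabet is None:
        alphabet = {s for s in column.values() if s != GAP}
    alphabet = tuple(sorted(alphabet))
    _check_column(tree.taxa, column, alphabet)
    full = frozenset(alphabet)
    sets: Dict[object, frozenset] = {}
    unions = 0
    for v in reversed(tree.canonical_order):
        if tree.is_leaf(v):
            s = column[tree.leaf_label[v]]
            sets[v] = full if s == GAP else frozenset((s,))
        else:
            a, b = (sets[w] for w in tree.graph.successors(v))
            inter = a & b
            if inter:
                sets[v] = inter
            else:
                sets[v] = a | b
                unions += 1
    return FitchAnnotation(tree, alphabet, sets, unions, sets[tree.root])


def fitch_extension(tree: PhyloTree, annotation: FitchAnnotation) -> Dict[object, str]:
    """Top-down phase: one optimal extension from a bottom-up annotation.

    The root takes the smallest state of its set; a child keeps its parent's
    state when available, otherwise the smallest state of its own set.  The
    number of parent/child mismatches equals ``union_count``, and the
    extension never contains a gap.
    """
    ext: Dict[object, str] = {}
    for v in tree.canonical_order:
        s = annotation.sets[v]
        if v == tree.root:
            ext[v] = min(s)
        else:
            (parent,) = tree.graph.predecessors(v)
            ext[v] = ext[parent] if ext[parent] in s else min(s)
    return ext


def tree_score(tree: PhyloTree, aln: Alignment) -> int:
    """Parsimony score of a tree: sum of its column scores."""
    if tree.taxa != tuple(sorted(aln.taxa)):
        raise ValueError("tree and alignment taxa differ")
    scorer = NetworkScorer(tree, aln)
    total, _, _ = scorer.score(frozenset())
    return total


# -- fast switching scorer ---------------------------------------------------


class NetworkScorer:
    """Scores switchings of one (network, alignment) pair.

    Precomputes a reverse topological order and per-column leaf state masks;
    ``score(removed_arcs)`` then runs one mask-based Fitch pass per column
    over the switching subtree (pruned unlabelled parts propagate as None).
    """

    def __init__(self, net: PhyloNetwork, aln: Alignment):
        if net.taxa != tuple(sorted(aln.taxa)):
            raise ValueError("network and alignment taxa differ")
        self.net = net
        self.aln = aln
        self.alphabet = tuple(sorted(aln.alphabet))
        self.index = {s: i for i, s in enumerate(self.alphabet)}
        self.full = (1 << len(self.alphabet)) - 1
        self.rev_topo = list(reversed(list(nx.topological_sort(net.graph))))
        self.succ = {v: tuple(net.graph.successors(v)) for v in net.graph}
        self.leaf_masks: List[Dict[object, int]] = []
        for j in range(aln.m):
            col = aln.column(j)
            masks = {}
            for v, t in net.leaf_label.items():
                s = col[t]
                masks[v] = self.full if s == GAP else 1 << self.index[s]
            self.leaf_masks.append(masks)

    def score(self, removed: frozenset) -> Tuple[int, List[int], List[int]]:
        """Return (total score, per-column scores, per-column root masks)."""
        per_col: List[int] = []
        roots: List[int] = []
        root = self.net.root
        for masks in self.leaf_masks:
            values: Dict[object, Optional[int]] = {}
            unions = 0
            for v in self.rev_topo:
                lm = masks.get(v)
                if lm is not None:
                    values[v] = lm
                    continue
                got = []
                for w in self.succ[v]:
                    if (v, w) in removed:
                        continue
                    m = values[w]
                    if m is not None:
                        got.append(m)
                if not got:
                    values[v] = None
                elif len(got) == 1:
                    values[v] = got[0]
                else:
                    a, b = got
                    inter = a & b
                    if inter:
                        values[v] = inter
                    else:
                        values[v] = a | b
                        unions += 1
            per_col.append(unions)
            roots.append(values[root])
        return sum(per_col), per_col, roots


@dataclass(frozen=True)
class MPResult:
    """A certified most parsimonious displayed tree."""

    score: int
    tree: DisplayedTree
    switching: Switching
    per_column: Tuple[int, ...]


def _check_cap(net: PhyloNetwork, cap: int) -> None:
    if 2 ** net.n_reticulations > cap:
        raise EnumerationCapError(
            f"2^{net.n_reticulations} switchings exceed cap {cap}"
        )


def network_score_shared(
    net: PhyloNetwork,
    aln: Alignment,
    cap: int = DEFAULT_CAP,
    switchings: Optional[Iterable[Switching]] = None,
) -> MPResult:
    """Shared-tree softwired parsimony score of a network.

    Exact minimum of the tree score over all displayed trees (all
    switchings, or an explicit iterable of switchings); ties broken by the
    lexicographically smallest switching.
    """
    if switchings is None:
        _check_cap(net, cap)
        switchings = enumerate_switchings(net)
    scorer = NetworkScorer(net, aln)
    best: Optional[Tuple[int, Switching, Tuple[int, ...]]] = None
    for s in switchings:
        total, per_col, _ = scorer.score(s.removed_arcs)
        if best is None or total < best[0] or (total == best[0] and s < best[1]):
            best = (total, s, tuple(per_col))
    if best is None:
        raise ValueError("no switchings supplied")
    total, s, per_col = best
    return MPResult(total, extract_displayed_tree(net, s), s, per_col)


@dataclass(frozen=True)
class PerColumnResult:
    score: int
    per_column: Tuple[int, ...]
    switchings: Tuple[Switching, ...]  # a minimizing switching per column


def network_score_percolumn(
    net: PhyloNetwork,
    aln: Alignment,
    cap: int = DEFAULT_CAP,
) -> PerColumnResult:
    """Per-column softwired score: each character follows its own displayed tree."""
    _check_cap(net, cap)
    scorer = NetworkScorer(net, aln)
    best_per_col: List[Optional[int]] = [None] * aln.m
    best_sw: List[Optional[Switching]] = [None] * aln.m
    for s in enumerate_switchings(net):
        _, per_col, _ = scorer.score(s.removed_arcs)
        for j, sc in enumerate(per_col):
            if best_per_col[j] is None or sc < best_per_col[j]:
                best_per_col[j] = sc
                best_sw[j] = s
    return PerColumnResult(sum(best_per_col), tuple(best_per_col), tuple(best_sw))


# -- gap-removal consistency -------------------------------------------------


@dataclass(frozen=True)
class GapRemovalReport:
    """Check that cherry-encoding gaps shifts every displayed tree's score by k."""

    k: int
    consistent: bool
    optimum: int
    optimum_gapless: int
    n_switchings: int


def check_gap_removal(
    net: PhyloNetwork,
    aln: Alignment,
    cap: int = DEFAULT_CAP,
) -> GapRemovalReport:
    """Verify the gap-encoding identity l_{A'}(g(T)) = l_A(T) + k.

    Splits every taxon into a cherry (gap becomes the 0/1 cherry), then
    compares the score of every displayed tree before and after; also
    reports both optima, which must differ by exactly the gap count k.
    """
    from .reduction import remove_gaps

    _check_cap(net, cap)
    net2, aln2, g = remove_gaps(net, aln)
    k = aln.gap_count
    scorer1 = NetworkScorer(net, aln)
    scorer2 = NetworkScorer(net2, aln2)
    consistent = True
    opt1: Optional[int] = None
    opt2: Optional[int] = None
    count = 0
    for s in enumerate_switchings(net):
        t1, _, _ = scorer1.score(s.removed_arcs)
        t2, _, _ = scorer2.score(g(s).removed_arcs)
        if t2 != t1 + k:
            consistent = False
        opt1 = t1 if opt1 is None else min(opt1, t1)
        opt2 = t2 if opt2 is None else min(opt2, t2)
        count += 1
    return GapRemovalReport(k, consistent and opt2 == opt1 + k, opt1, opt2, count)
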