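"""Seeded random generators for property suites and simulations.

Networks are grown bottom-up from n leaf components by a random sequence
of joins: a binary join merges two components under a new tree node, a
gall join merges three components under a 4-node gall (cycle of a top
node, two side nodes and a reticulation, each side and the reticulation
feeding one component).  Exactly r gall joins are performed, so the result
is a valid binary level-1 network with r galls; feasibility requires
n >= 2r + 1.  All draws come from one ``random.Random(seed)`` instance, so
a configuration reproduces its outputs exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import networkx as nx

from .core import GAP, Alignment, PhyloNetwork, PhyloTree

__all__ = ["GeneratorConfig", "random_level1_network", "random_alignment"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random network / alignment generators."""

    seed: int
    n_taxa: int = 6
    n_reticulations: int = 1
    n_characters: int = 2
    prob_range: Optional[Tuple[float, float]] = None  # arc change probabilities
    gap_fraction: float = 0.0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")
        if self.n_reticulations < 0:
            raise ValueError("negative reticulation count")
        if self.n_taxa < 2 * self.n_reticulations + 1:
            raise ValueError(
                f"{self.n_reticulations} galls need at least "
                f"{2 * self.n_reticulations + 1} taxa (got {self.n_taxa})"
            )
        if self.prob_range is not None:
            lo, hi = self.prob_range
            if not (0.0 <= lo <= hi <= 0.5):
                raise ValueError("prob_range must lie within [0, 1/2]")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must lie in [0, 1)")


def random_level1_network(cfg: GeneratorConfig) -> PhyloNetwork:
    """A seeded random binary level-1 network with exactly the configured galls."""
    rng = random.Random(cfg.seed)
    g = nx.DiGraph()
    labels = {}
    next_id = 0

    def new() -> int:
        nonlocal next_id
        v = next_id
        next_id += 1
        g.add_node(v)
        return v

    comps = []
    for i in range(cfg.n_taxa):
        v = new()
        labels[v] = f"t{i + 1:02d}"
        comps.append(v)

    galls_left = cfg.n_reticulations
    while len(comps) > 1:
        # a gall join consumes two extra components; keep enough merges ahead
        must_gall = galls_left > 0 and len(comps) == 2 * galls_left + 1
        may_gall = galls_left > 0 and len(comps) >= 3
        do_gall = must_gall or (may_gall and rng.random() < 0.5)
        if do_gall:
            a, b, c = rng.sample(range(len(comps)), 3)
            ra, rb, rc = comps[a], comps[b], comps[c]
            for i in sorted((a, b, c), reverse=True):
                comps.pop(i)
            top, s1, s2, ret = new(), new(), new(), new()
            g.add_edges_from(
                [(top, s1), (top, s2), (s1, ret), (s2, ret), (s1, ra), (s2, rb), (ret, rc)]
            )
            comps.append(top)
            galls_left -= 1
        else:
            a, b = rng.sample(range(len(comps)), 2)
            ra, rb = comps[a], comps[b]
            for i in sorted((a, b), reverse=True):
                comps.pop(i)
            v = new()
            g.add_edge(v, ra)
            g.add_edge(v, rb)
            comps.append(v)

    arc_prob = None
    if cfg.prob_range is not None:
        lo, hi = cfg.prob_range
        arc_prob = {a: rng.uniform(lo, hi) for a in sorted(g.edges())}
    cls = PhyloTree if cfg.n_reticulations == 0 else PhyloNetwork
    return cls(g, labels, arc_prob)


def random_alignment(cfg: GeneratorConfig, taxa: Sequence[str]) -> Alignment:
    """Seeded binary alignment; every column is surjective onto {0, 1}.

    Columns that miss a state among their non-gap entries are redrawn.
    Gaps appear independently at ``cfg.gap_fraction``.
    """
    rng = random.Random(cfg.seed ^ 0x5EED)
    taxa = tuple(taxa)
    cols = []
    for _ in range(cfg.n_characters):
        while True:
            col = []
            for _ in taxa:
                if cfg.gap_fraction and rng.random() < cfg.gap_fraction:
                    col.append(GAP)
                else:
                    col.append(rng.choice("01"))
            present = set(col) - {GAP}
            if present == {"0", "1"}:
                break
        cols.append(col)
    rows = tuple("".join(cols[j][i] for j in range(cfg.n_characters)) for i in range(len(taxa)))
    return Alignment(taxa, rows, frozenset({"0", "1"}))
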