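"""Readers and writers: eNewick networks, Newick trees, and alignments.

The eNewick dialect used here tags reticulation nodes ``#Hk``; the first
occurrence of a tag may carry the node's subtree, any other occurrence is a
bare reference.  The branch-length slot (``:x``) stores the arc's change
probability in [0, 1/2]; either every arc carries one or none does.  An
extended three-field slot ``:p:support:gamma`` is accepted, but the
inheritance probability in the third field is ignored with a logged notice
(tree likelihood does not depend on it).

Alignments are matrices of single-character states over an alphabet plus
the gap symbol ``-``; supported formats are FASTA, relaxed sequential
PHYLIP and CSV (taxon in the first cell of each row, one column per
character).
"""

from __future__ import annotations

import csv
import io as _io
import logging
import os
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import networkx as nx
from Bio import SeqIO

from .core import GAP, Alignment, NetworkStructureError, PhyloNetwork, PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_enewick",
    "write_enewick",
    "read_newick_tree",
    "write_newick",
    "read_alignment",
    "write_alignment",
]

_LABEL_CHARS = re.compile(r"[^(),:;]")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.graph = nx.DiGraph()
        self.leaf_label: Dict[object, str] = {}
        self.arc_prob: Dict[Tuple[object, object], float] = {}
        self.hybrid: Dict[str, int] = {}  # tag -> node id
        self.hybrid_has_subtree: Dict[str, bool] = {}
        self._next = 0
        self._gamma_notice = False

    def new_node(self) -> int:
        v = self._next
        self._next += 1
        self.graph.add_node(v)
        return v

    def peek(self) -> str:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch: str) -> None:
        if self.peek() != ch:
            raise ValueError(f"malformed eNewick: expected {ch!r} at position {self.pos}")
        self.pos += 1

    def read_label(self) -> str:
        out = []
        while self.pos < len(self.text) and _LABEL_CHARS.match(self.text[self.pos]):
            out.append(self.text[self.pos])
            self.pos += 1
        return "".join(out).strip()

    def read_fields(self) -> Optional[float]:
        """Read the optional ``:p[:support[:gamma]]`` suffix; return p."""
        if self.peek() != ":":
            return None
        fields: List[str] = []
        while self.peek() == ":":
            self.pos += 1
            fields.append(self.read_label())
        if len(fields) >= 3 and fields[2] != "" and not self._gamma_notice:
            logger.info(
                "inheritance probabilities present in input; ignored "
                "(irrelevant for displayed-tree scores)"
            )
            self._gamma_notice = True
        if fields[0] == "":
            raise ValueError("empty branch-probability slot")
        p = float(fields[0])
        if not (0.0 <= p <= 0.5):
            raise ValueError(f"change probability {p} outside [0, 1/2]")
        return p

    def parse_subtree(self) -> Tuple[int, Optional[float]]:
        children: List[Tuple[int, Optional[float]]] = []
        if self.peek() == "(":
            self.take("(")
            children.append(self.parse_subtree())
            while self.peek() == ",":
                self.take(",")
                children.append(self.parse_subtree())
            self.take(")")
        label = self.read_label()
        prob = self.read_fields()

        name, tag = label, None
        if "#" in label:
            name, tag = label.split("#", 1)
            if not tag:
                raise ValueError("empty hybrid tag")

        if tag is not None:
            if tag in self.hybrid:
                node = self.hybrid[tag]
                if children and self.hybrid_has_subtree[tag]:
                    raise ValueError(f"hybrid #{tag} defined with a subtree twice")
            else:
                node = self.new_node()
                self.hybrid[tag] = node
                self.hybrid_has_subtree[tag] = False
            if children:
                self.hybrid_has_subtree[tag] = True
        else:
            node = self.new_node()

        for child, p in children:
            if self.graph.has_edge(node, child):
                raise ValueError("parallel arcs are not allowed")
            self.graph.add_edge(node, child)
            if p is not None:
                self.arc_prob[(node, child)] = p
        if name and not children and tag is None:
            self.leaf_label[node] = name
        elif name and tag is not None:
            # a named hybrid node; names on reticulations are dropped
            pass
        return node, prob

    def parse(self) -> PhyloNetwork:
        root, prob = self.parse_subtree()
        if prob is not None:
            raise ValueError("the root may not carry a branch probability")
        self.take(";")
        if self.peek():
            raise ValueError("trailing characters after ';'")
        for tag, has in self.hybrid_has_subtree.items():
            if not has and self.graph.out_degree(self.hybrid[tag]) == 0:
                raise ValueError(f"hybrid #{tag} never given a subtree or leaf child")
        n_arcs = self.graph.number_of_edges()
        if self.arc_prob and len(self.arc_prob) != n_arcs:
            raise ValueError("mixed presence of branch probabilities (all arcs or none)")
        return PhyloNetwork(
            self.graph,
            self.leaf_label,
            self.arc_prob if self.arc_prob else None,
        )


def read_enewick(text: str) -> PhyloNetwork:
    """Parse an eNewick string into a validated :class:`PhyloNetwork`."""
    return _Parser(text).parse()


def read_newick_tree(text: str) -> PhyloTree:
    """Parse a (hybrid-free) Newick string into a :class:`PhyloTree`."""
    net = read_enewick(text)
    return PhyloTree.from_network(net)


def _fmt_prob(p: float) -> str:
    return repr(p)


def write_enewick(net: PhyloNetwork) -> str:
    """Serialize a network to eNewick; inverse of :func:`read_enewick`.

    Reticulations are tagged ``#H1..`` in canonical order; the canonically
    first parent's occurrence carries the subtree.
    """
    tags = {v: f"H{i + 1}" for i, v in enumerate(net.reticulations)}
    primary = {v: net.parents(v)[0] for v in net.reticulations}
    probs = net.arc_prob

    def render(v, parent) -> str:
        suffix = ""
        if parent is not None and probs is not None:
            suffix = ":" + _fmt_prob(probs[(parent, v)])
        if v in tags and parent is not None and parent != primary[v]:
            return f"#{tags[v]}{suffix}"
        if net.is_leaf(v):
            body = net.leaf_label[v]
        else:
            body = "(" + ",".join(render(w, v) for w in net.children(v)) + ")"
        if v in tags:
            body += f"#{tags[v]}"
        return body + suffix

    return render(net.root, None) + ";"


def write_newick(tree: PhyloTree) -> str:
    return write_enewick(tree)


# -- alignments --------------------------------------------------------------


def _as_text(source: Union[str, Path]) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source and os.path.exists(source):
        return Path(source).read_text()
    return source


def _parse_fasta(text: str) -> List[Tuple[str, str]]:
    records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    return [(r.id, str(r.seq)) for r in records]


def _parse_phylip(text: str) -> List[Tuple[str, str]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PHYLIP input")
    head = lines[0].split()
    if len(head) != 2:
        raise ValueError("PHYLIP header must be 'ntax nchar'")
    ntax, nchar = int(head[0]), int(head[1])
    out: List[Tuple[str, str]] = []
    i = 1
    for _ in range(ntax):
        if i >= len(lines):
            raise ValueError("fewer sequences than declared")
        parts = lines[i].split()
        i += 1
        name, seq = parts[0], "".join(parts[1:])
        while len(seq) < nchar:
            if i >= len(lines):
                raise ValueError(f"sequence for {name!r} shorter than declared")
            seq += "".join(lines[i].split())
            i += 1
        if len(seq) != nchar:
            raise ValueError(f"sequence for {name!r} longer than declared")
        out.append((name, seq))
    return out


def _parse_csv(text: str) -> List[Tuple[str, str]]:
    out = []
    for row in csv.reader(_io.StringIO(text)):
        if not row:
            continue
        name, states = row[0].strip(), [c.strip() for c in row[1:]]
        if any(len(c) != 1 for c in states):
            raise ValueError("CSV cells must hold single-character states")
        out.append((name, "".join(states)))
    if not out:
        raise ValueError("empty CSV input")
    return out


_PARSERS = {"fasta": _parse_fasta, "phylip": _parse_phylip, "csv": _parse_csv}


def read_alignment(
    source: Union[str, Path],
    format: str = "fasta",
    alphabet: Optional[Iterable[str]] = None,
) -> Alignment:
    """Read an alignment from a path or literal text.

    ``format`` is one of ``fasta``, ``phylip``, ``csv``; taxon order is
    preserved as given.  If ``alphabet`` is omitted it is inferred from the
    non-gap symbols present.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown alignment format {format!r}")
    pairs = _PARSERS[format](_as_text(source))
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon name")
    if alphabet is None:
        alphabet = {c for _, s in pairs for c in s if c != GAP}
    return Alignment(tuple(names), tuple(s for _, s in pairs), frozenset(alphabet))


def write_alignment(aln: Alignment, format: str = "fasta") -> str:
    if format == "fasta":
        return "".join(f">{t}\n{r}\n" for t, r in zip(aln.taxa, aln.rows))
    if format == "phylip":
        head = f"{aln.n} {aln.m}\n"
        return head + "".join(f"{t}  {r}\n" for t, r in zip(aln.taxa, aln.rows))
    if format == "csv":
        buf = _io.StringIO()
        w = csv.writer(buf)
        for t, r in zip(aln.taxa, aln.rows):
            w.writerow([t] + list(r))
        return buf.getvalue()
    raise ValueError(f"unknown alignment format {format!r}")
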