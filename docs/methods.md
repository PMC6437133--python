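# Methods

This note records the models implemented by `netmpl`, the numerical and
design choices that were genuinely open, and what the verification
harness does and does not establish.

## Objects

A *network* is a rooted binary DAG: one root (in 0, out 2), leaves (in 1,
out 0) bijectively labelled by the taxon set X, and otherwise tree nodes
(in 1, out 2) or reticulations (in 2, out 1).  The *level* is the maximum
number of reticulations in a biconnected component of the underlying
undirected graph; in a level-1 network every non-trivial component is a
*gall*: a simple cycle with one reticulation.  A *switching* keeps one
incoming arc per reticulation; cleanup (delete unlabelled outdegree-0
nodes iteratively, trim an outdegree-1 root chain, suppress remaining
indegree-1/outdegree-1 nodes) yields the *displayed tree*, and the
extraction records, per tree edge, the network arcs contracted into it.

Networks are exchanged as eNewick with `#Hk` hybrid tags.  No standard
exchange format is forced by the problem itself; eNewick was chosen
because common viewers read it, and the branch-length slot is reused for
the arc change probability (either all arcs carry one or none — mixed
presence is rejected as almost certainly a file error).  Inheritance
probabilities (a third `:` field) are accepted and ignored with a logged
notice: they parameterize network likelihood, which is out of scope here,
and do not affect any displayed tree's likelihood.

## Parsimony

Column scores use Fitch's bottom-up phase over arbitrary finite alphabets;
the union count equals the column score.  Gap symbols are wildcards: a gap
leaf receives the full alphabet, so it never forces a mutation (and
extensions never contain gaps).  Two choices the classical algorithm
leaves open are fixed deterministically:

- **Top-down tie rule.**  Where a state must be picked from a set (the
  root, or a child whose set excludes its parent's state), the
  lexicographically smallest member is taken.  Any member is optimal; the
  rule only pins down which optimal extension is reported.
- **Reported extensions** are those generable by Fitch's phases.  Optimal
  extensions outside that family exist but are not enumerated.

Network scores minimize over switchings.  Scoring a switching runs the
bottom-up pass directly on the switching subtree of the network —
state sets are invariant under suppressing degree-two nodes and pruning
unlabelled hanging subtrees, so no per-switching tree extraction is
needed, which is what makes full 4^|E| instance enumerations cheap.
Enumeration order is lexicographic over a canonical node order (DFS
preorder, children ordered by smallest descendant taxon), which makes
tie-breaking ("lexicographically smallest optimal switching")
reproducible.  Enumeration is guarded by a configurable cap (default
2^20 switchings); exceeding it raises rather than truncating silently.
Switchings, not topologies, are deduplicated — distinct switchings with
equal displayed topology have equal scores, so the minimum is unaffected.

## Likelihood

The symmetric two-state model: root states equiprobable, each edge flips
the state with probability `p_e ≤ 1/2`.  Per character, the likelihood is
the extension sum; `tree_log_likelihood` computes it by the standard
post-order conditional-likelihood recursion with **per-node rescaling in
log space**.  The rescaling matters: the ML⇒MP checks run at constant
probabilities around 1e-30, where unscaled products underflow doubles.
`p_e = 0` is handled exactly (an impossible character yields −inf).  The
brute-force extension sum is retained as the independent reference; the
two agree to 1e-10 relative error on their overlapping domain (seeded
suite in the tests).  The root prior is fixed at (1/2, 1/2) and is not
configurable — it is part of the model, not a tuning knob.

Contraction of a two-arc path composes probabilities as
`p = p1(1−p2) + (1−p1)p2`, which is commutative, associative, has
identity 0 and absorbing element 1/2, and never leaves [0, 1/2].  For a
contracted edge with image arcs E′(e), `max p′ < p_e < Σ p′` holds
strictly when |E′(e)| ≥ 2 and all probabilities are in (0, 1/2); when
|E′(e)| = 1 the contracted probability *equals* the single arc's, so the
implementation asserts equality there instead of strict inequality.  (At
probabilities near 1e-30 the strict upper bound also collides with double
rounding — `2c − 2c²` rounds to `2c` — which the tests tolerate.)

The parsimony link: with every arc at constant `c`, a displayed tree's
log-likelihood is bracketed by `−2mn·ln2 + l·ln c` and
`mn·ln2 + 2mn·ln d + l·ln c` (l its parsimony score, d the network
height), so likelihood order agrees with parsimony order once
`c < d^(−2mn) 2^(−3mn)`.  `verify_ml_is_mp` refuses a `c` at or above that
threshold and defaults to half of it.  The threshold is computed in log
space; the actual `c` must still be representable as a positive double,
which holds comfortably at the problem sizes used (n ≤ 6, m ≤ 2 give
c ≈ 1e-30; doubles reach 1e-308).

## The reduction harness

`build_instance` turns a cubic graph G into (N, A): a left-deep
caterpillar over the lexicographically sorted edges, each leaf replaced by
a copy of the edge gadget; one alignment column per vertex, edge
e = {u, v} (u the smaller endpoint) contributing `1,1,0,0,0,1` at u,
`0,1,1,1,0,0` at v and gaps elsewhere.  Caterpillar and column order are
arbitrary for the score (asserted implicitly by the identities holding);
sorting makes output canonical.

**Gadget derivation.**  The gadget's wiring is specified only by its
behaviour, so it is derived by exhaustive search: enumerate every term of
the grammar `S ::= leaf | internal(S,S) | gall(A=S,B=S,C=S)` on the six
labelled leaves with exactly two galls, where a gall is the 4-node cycle
(top, two side nodes feeding A and B, reticulation feeding C) — the only
gall shape with exactly three outgoing arcs in a binary network.  A term
is accepted iff, on the two informative columns, exactly two of its four
switchings attain the minimum score with complementary singleton root
sets ({0},{1}) and ({1},{0}), and the other two switchings share a
strictly larger score (the shared-score requirement makes "the suboptimal
score" well defined).  The first accepted term in the fixed enumeration
order is canonical:

    (((1,(2)#H1),(#H1,3)),((4,(5)#H2),(#H2,6)));

with switching scores 4, 4 (optimal) and 5, 5.  Search cost is about a
second and the result is cached per process.  Candidate switchings are
scored directly on the term algebra (keeping the s1 arc displays
((A,C),B), keeping s2 displays (A,(B,C))), independently of the network
scorer; the acceptance script re-scores the four switchings of the built
network with the generic Fitch machinery, so the two routes check each
other.

**Back-mapping.**  Given any switching of an instance, each gadget not in
an optimal state is replaced by whichever of the two optimal states is
cheaper (never increasing the total, per the replacement argument checked
on sampled switchings); the orientation then reads off each gadget's root
state — state 1 in an endpoint's column orients the edge out of that
endpoint.  The normalized mutation count p′ satisfies
`sources + sinks = 7|V| − p′` on every sampled switching.

**Gap removal** splits each taxon x into a cherry x.1/x.2; a gap becomes
the (0, 1) cherry whose forced mutation makes the parent state free.
Switchings transfer across unchanged (the reticulations are untouched),
giving the displayed-tree bijection; every displayed tree's score grows by
exactly the gap count, checked for all 4096 switchings of the K₄ instance.

**Verification modes.**  `verify_reduction` brute-forces the score
identity in `full` mode (all 4^|E| switchings; used for K₄, |E| = 6) or
`good` mode (2^|E| optimal-gadget switchings; used beyond |E| = 6, e.g.
K₃,₃ and the prism).  That the restriction is lossless is itself a
consequence of the replacement argument and is corroborated by full and
good modes agreeing on K₄.

## Random generators

The spec'd study conditions (property suites over "seeded random level-1
networks") are produced by composing r ternary gall joins and n−1−2r
binary joins bottom-up from n leaves, all draws from one
`random.Random(seed)`.  This is the natural generator once one observes
that a 4-node gall consumes three subtrees, so "inserting a gall on a tree
edge" cannot yield a binary network; feasibility is n ≥ 2r + 1.  Arc
probabilities, when requested, are uniform on a configured subinterval of
[0, 1/2] (default study range 0.05–0.45, away from the degenerate
endpoints).  Random alignments draw binary states uniformly and redraw any
column that is not surjective onto {0, 1} among its non-gap entries,
matching the definition of a character as a surjective map.

What the generators do *not* emulate: real sequence data has correlated
columns, non-uniform base composition, many states, and networks inferred
from data rather than sampled uniformly from a grammar.  Passing suites
therefore certify the *combinatorics and numerics* of the implementation
(scores, enumerations, identities, stability), not statistical behaviour
on biological alignments.

## Problem sizes and limitations

The harness runs at the sizes the identities are stated for: K₄ fully
enumerated (4096 switchings, also after gap doubling to 72 taxa), K₃,₃
and the prism in good-switchings mode, oracle suites at ≤ 8 leaves and
≤ 3 characters, and 50 ML⇒MP networks at n ≤ 6, m ≤ 2 — the whole suite
completes in a few seconds.  Everything is exact enumeration: no
heuristics, no FPT dynamic program, no ILP, and no approximation of msso;
networks with indegree > 2 reticulations, non-binary nodes, network (as
opposed to displayed-tree) likelihood, and likelihood with gap symbols
are out of scope.  The per-column parsimony variant is implemented for
comparison but all identities use the shared-tree definition.
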