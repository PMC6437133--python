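# netmpl

Exact search for **most parsimonious (MP)** and **most likely (ML)** trees
displayed by rooted binary **level-1 phylogenetic networks**, together with
the hardness-reduction construction that doubles as an end-to-end
verification harness.

## The problem

Rooted phylogenetic networks generalize trees by allowing reticulation
nodes (indegree 2, outdegree 1), which model hybridization, recombination
and horizontal transfer.  A network *N* *displays* a tree *T* when a
subdivision of *T* embeds in *N*; equivalently, some *switching* — a choice
of one retained incoming arc per reticulation — cleans up to *T*.  Given a
multiple alignment *A* for the taxa of *N*, a natural question is which
displayed tree explains *A* best:

- **Softwired parsimony.**  The score of a tree is the usual small-parsimony
  score, `l_A(T) = Σ_f l_f(T)`, computed per column by Fitch's algorithm
  (gap symbols are wildcards: a gap leaf receives the whole state set).
  The network score is `min_T Σ_f l_f(T)` over displayed trees *T*
  (the shared-tree definition; the per-column variant
  `Σ_f min_T l_f(T)` is also provided and never exceeds it).
- **Likelihood.**  Under the symmetric two-state (Cavender–Farris) model
  each arc *e* carries a change probability `p_e ≤ 1/2`; suppressing a
  degree-two node composes probabilities along the path as
  `p = p₁(1−p₂) + (1−p₁)p₂`.  A network with arc probabilities therefore
  displays *trees with edge probabilities*, and an ML displayed tree
  maximizes `L_A(T, p) = Π_f L_f(T, p)` with equiprobable root states.

Both optimization problems are computationally hard already for level-1
networks over binary characters, so `netmpl` implements the exact
`2^r`-switching enumeration (practical whenever the reticulation number
*r* is moderate) and, as a correctness harness, the reduction that encodes
**MAX-SOURCE-SINKS-ORIENTATION (msso)** on cubic graphs into these
problems:

- every edge of a cubic graph *G* becomes a fixed 6-taxon, 2-reticulation
  *edge gadget* hanging off a caterpillar, with two informative alignment
  columns (`1,1,0,0,0,1` and `0,1,1,1,0,0`) and gaps elsewhere;
- the gadget's two cheapest switchings (4 mutations each; the other two
  cost 5) force complementary root states and encode the edge's two
  orientations, giving the identity `mp(N, A) = 7|V| − msso(G)`;
- gaps can be eliminated by splitting every taxon into a cherry, which
  shifts every displayed tree's score by exactly the gap count
  `k = 6|V|(|E|−3)`;
- at constant arc probability `c < d^(−2mn)·2^(−3mn)` (with *d* the network
  height, *m* the character count and *n* the taxon count), every ML
  displayed tree is also MP, which links the two problems.

The gadget's wiring is **derived, not transcribed**: an exhaustive search
over all level-1 networks on six labelled leaves with two 4-node galls
accepts exactly the switching behaviour above (see `docs/methods.md`).

## Worked example

```python
from netmpl import read_enewick, Alignment
from netmpl.parsimony import network_score_shared
from netmpl.likelihood import verify_ml_is_mp
from netmpl.io import write_enewick

net = read_enewick("((a,(b)#H1),(#H1,c));")          # one gall, taxa a,b,c
aln = Alignment(("a", "b", "c"), ("01", "00", "10"), frozenset("01"))

mp = network_score_shared(net, aln)
print(mp.score, write_enewick(mp.tree.tree), mp.switching.choices)
rep = verify_ml_is_mp(net, aln)                       # constant-c ML == MP?
print(rep.ok, rep.mp_score, rep.ml_tree_parsimony)
```

prints

```
2 ((a,b),c); (0,)
True 2 2
```

meaning: the cheapest displayed tree of the network costs 2 mutations, it
is `((a,b),c)` obtained by keeping the first incoming arc of the
reticulation, and with every arc set to the same sufficiently small change
probability the most likely displayed tree indeed attains that most
parsimonious score.

The same functionality is exposed on the command line:

```sh
netmpl gadget                      # derived edge gadget + switching table
netmpl mp-tree --network net.enwk --alignment aln.fasta --out report.json
netmpl ml-tree --network net.enwk --alignment aln.fasta --out report.json
netmpl verify-ml-mp --network net.enwk --alignment aln.fasta
netmpl msso --graph k4.edgelist    # brute-force orientation optimum
netmpl reduce --graph k4.edgelist --out-network n.enwk --out-alignment a.fasta
netmpl verify-reduction --graph k4.edgelist --mode full
netmpl random-net --seed 3 --taxa 6 --reticulations 2
```

For example `netmpl verify-reduction --graph k4.edgelist --mode full`
brute-forces all 4096 switchings of the 36-taxon instance built from K₄
and confirms `mp(N, A) = 26 = 7·4 − msso(K₄)` with `msso(K₄) = 2`, and
`98 = 26 + 72` after gap removal.

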