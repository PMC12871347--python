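# Methods

This note documents the modelling and numerical choices behind the
package: what is computed, under which assumptions, which parameters
matter, and what the synthetic data does and does not establish.

## Problem and labeling semantics

An edge of a binary phylogeny is identified by its split — the bipartition
of the leaf set obtained by deleting it.  An edge is an *MP edge* for an
alignment if its split occurs in at least one maximum-parsimony (MP)
topology, and a *non-MP edge* otherwise.  Pendant edges induce trivial
splits present in every tree, so they are always MP and are excluded from
labels, loss and evaluation; a tree with $n$ leaves contributes its $n-3$
internal edges.

Labels are exact whenever the MP set is exact.  The package scores all
$(2n-5)!!$ unrooted topologies with the Fitch algorithm for $n \le 10$
(945 topologies at $n=7$, ~10,400 at $n=8$; site patterns are collapsed to
weighted unique columns first).  Beyond that, an SPR hill-climb from
random starts collects the plateau of equally parsimonious trees (up to
200 topologies, the same cap applied when subsampling trees for
perturbation).  Plateau-derived labels mean "in the discovered MP
plateau": the search has no optimality certificate, and on signal-free
(i.i.d. uniform) alignments it can strand in local optima.  On simulated
alignments with genuine tree signal at 100 sites we observe it recovering
the exact MP set whenever this is checkable ($n \le 9$); the residual
possibility of missed MP splits is a known limitation of heuristic
labeling at scale.

## Trees

All pipeline trees are binary and rooted in a leaf, so each non-root node
names its incoming edge.  Children are ordered by the smallest leaf label
in their subtree and nodes are numbered in preorder, giving every topology
one canonical representation — tensor layouts are therefore reproducible
byte for byte.  Conventions the problem itself does not fix:

- default root leaf: the lexicographically smallest label;
- branch lengths are parsed and preserved but ignored by everything except
  the simulator (parsimony is topology-only);
- uniform random topologies are sampled by sequential leaf attachment
  (uniform over the $(2n-3)!!$ rooted shapes); candidate trees marginalise
  the root position away, which leaves the uniform distribution over the
  $(2n-5)!!$ unrooted topologies, and re-root at the smallest leaf.

## Tensor encodings

Mutation channels are ordered $[\mu_A, \mu_G, \mu_C, \mu_T]$ — **A, G, C,
T, not alphabetical**.  This is a single line of code but an
interoperability trap; `dpvt.encoding.CHANNELS` is the single source of
truth.  A mutation $i \to j$ (away from the root) sets $\mu_i=-1,
\mu_j=+1$; no mutation is the zero vector, and reading an edge against its
orientation negates the entry.

The mutation tensor has shape $(n-3) \times N \times 4$ — internal edges
only, rows ordered by the edge's child-node preorder index.  Pendant edges
carry real mutations but have no rows; since the recurrent units consume
pendant edges as inputs, encoded examples carry an auxiliary per-node
array (shape $V \times N \times 4$, zero row for the root) from which both
tensors are slices.  Padded sites are zero vectors, indistinguishable from
"no mutation" by design: masks, not sentinels, carry the distinction.

The traversal tensor has shape $2 \times (n-3) \times 3$.  Slice 0
(bottom-up, a postorder over internal edges) stores $[i_x, i_y, i_v]$ with
$v$ the edge's lower node and $x, y$ its children.  Slice 1 (top-down, a
preorder) stores $v$ = the edge's upper node, $x$ = $v$'s parent, $y$ =
the sibling edge's child node.  The visited edge's own lower node is *not*
in the slice-1 row; because the top-down visit order is by ascending lower
node index and both slices cover the same edge set, it is recovered from
slice 0 — the pair of tensors stays self-contained.

## Network

The recurrent unit maps $2(d+4) \to H \to d$ with one ReLU ($d=64$
per-direction feature width, $H=256$).  Unit inputs are concatenated as
(feature, mutation, feature, mutation) with the two contributing edges
ordered by the preorder index of their child nodes.  The upward and
downward passes use **separate** unit weights by default: their inputs are
differently signed and sourced, and nothing forces the two maps to
coincide (`share_units=True` restores sharing).  Because mutation signs
depend on the root-away orientation, predictions are root-dependent —
this is a method for rooted trees, not an invariance to be tested.

Pooling over sites is masked averaging, masked elementwise maximum, or a
transformer encoder over the site axis followed by masked averaging.
Transformer defaults: 1 pre-norm layer, 4 heads, model width $2d=128$,
feed-forward width 512, no positional encoding (alignment sites are
exchangeable under parsimony, and the block must stay
permutation-equivariant).  The attention output projection and the second
feed-forward layer are zero-initialised, so the block is exactly the
identity at initialisation; with one site, all three pooling modes then
return that site's feature unchanged.  Other weights use fan-in-scaled
normal initialisation from a recorded seed.

The network, its gradients, and Adam are implemented in a small
reverse-mode autodiff module on NumPy arrays (float64).  Gradient
correctness is established against central finite differences; note that
finite differences themselves are unreliable exactly at ReLU kinks, which
zero-initialised biases touch at the first step.

## Training and evaluation

Defaults: learning rate $5\times10^{-5}$, batch size 4, 200 epoch cap,
early stopping when validation loss has not improved for 5 consecutive
epochs, returning the best-validation-loss checkpoint.  The validation
split (10%) is drawn at the *alignment* level: trees from one alignment
share an MP-tree collection, and splitting at the tree level would leak
labels across the split.  Loss is binary cross-entropy over unmasked
internal edges, computed from logits in the numerically stable form.

AUROC pools all unmasked internal edges of all test trees into one ranking
(micro-pooling; per-tree macro-averaging would weight small trees up, and
pooling is the simplest consistent reading of a single per-dataset
number).  The reversion baseline flags an edge when any site mutates on it
to a state already present, at that site, in a strict ancestor on the root
path; it uses Fitch-reconstructed ancestral sequences — the pipeline has
no other ancestral sequences — and needs no training.

## Synthetic data

The simulator emulates the study conditions end to end: Jukes–Cantor
evolution (site change probability $\tfrac{3}{4}(1-e^{-4t/3})$ along a
branch of length $t$) down a uniform random topology with i.i.d.
exponential branch lengths, followed by the parsimony filters — sites with
gaps or ambiguity codes, constant sites, sites where a single sequence
deviates from all others, and duplicate sequences are removed.  Dropping a
duplicate can render further sites uninformative, so the ordered filter
pass iterates to a fixpoint; this makes filtering idempotent.  Simulation
oversizes by a factor of two in length and five extra sequences, trims
back to target after filtering, and retries (20 attempts) when the target
dimensions are not reached.

Numerical defaults, fixed once:

- exponential branch-length mean 0.15 expected substitutions per site —
  chosen so that twice-length simulations reliably survive filtering at
  the dimensions used here (about half of simulated sites are
  parsimony-informative in the 8–19 taxon range); zero-length branches are
  legal (the child copies the parent), negative lengths are errors;
- SPR perturbation: $\lfloor n/10 \rfloor$ moves, clamped to a minimum of
  1 so that small-$n$ exact-label datasets contain non-MP edges at all;
  moves are uniform over (prune, regraft) pairs, and regrafts onto the
  original position are rejected — otherwise a "move" can be vacuous;
- bounded-depth subtree replacement: depth $d = \max(1, \lfloor
  \text{tree depth}/2 \rfloor)$ of the input tree; the replacement loop
  repeats until at least one third of internal edges are non-MP, with a
  100-attempt budget (degenerate alignments where every topology is MP
  make the target unreachable and raise an explicit error);
- retry budgets and seeds are part of the configuration; a master seed
  fans out to stage seeds via `SeedSequence`, so every stage reproduces
  independently.

What passing tests on these data do **not** show: the simulated conditions
match real data only in structure, not distribution.  Alignments here are
gap-free, site-homogeneous, and evolved under the simplest substitution
model on moderate trees; empirical alignments bring rate heterogeneity,
indels and ambiguity codes, database-scale filtering, and far larger MP
plateaus.  Model quality on such data is untested by this suite.

## Problem sizes used by the verification runs

Exact enumeration bounds desk-scale experiments, so the packaged
experiments run at reduced size by design: exact-label datasets use 7–8
taxon alignments (30–100 sites); the larger-tree regime uses 14-taxon
alignments with plateau-search labels; baseline AUROC is pooled over at
least 2,000 internal edges; the learning-signal check trains
average-pooling models on 100 labeled trees for 30 full epochs (patience
equal to the epoch budget, so checkpoint selection rather than early
stopping decides the result).  The published-scale configuration
(hundreds of alignments, 25–50 taxa, 200 epochs) validates against the
config schema and is expressible with heuristic labeling, but is not
executed by the test suite.

## Known limitations

- Exact labels stop at $n \le 10$; plateau labels above that are
  best-effort and their fidelity is only spot-checked.
- The reversion baseline's AUROC is sensitive to tree depth and move
  count; at reduced $n$ its value drifts a few hundredths around the
  full-scale figures.
- Training on one CPU with float64 is orders of magnitude slower than a
  GPU implementation; the defaults are tuned for correctness and
  reproducibility, not throughput.
- No amino-acid states, ambiguity-code channels, branch-length channels,
  NNI/TBR perturbations, or likelihood-based variants.
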