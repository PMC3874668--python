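# Methods

This note documents the models and algorithms implemented in `mulrf`, the
choices made where the design was genuinely open, and what the tests do and
do not establish.

## Trees and splits

A *mul-tree* (`mulrf.trees.MulTree`) is an unrooted tree with every internal
vertex of degree ≥ 3 and a surjective map from leaves to labels; a *species
tree* (`SpeciesTree`) is the singly-labeled special case, kept binary when
used as a search state. A *split* is the bipartition of the leaf-label
multiset induced by an internal edge; pendant (trivial) splits are excluded
everywhere. For singly-labeled trees, equality of split sets is equivalent
to isomorphism, and the RF distance is the size of the symmetric difference
of the split sets. Mul-trees do not have this property — the test suite
freezes a 6-leaf pair with identical split sets but different shape, found
by exhaustive search — which is exactly why the gene-vs-species distance
goes through extension and differentiation rather than comparing mul-splits
directly.

Newick I/O accepts duplicate leaf labels, polytomies, quoted labels, and
branch lengths/internal labels (parsed, ignored by all distances). Rooted
inputs are read as their unrooted underlying tree; degree-2 vertices arising
anywhere (parsing, restriction, leaf deletion) are suppressed immediately.
Output is canonical: children are ordered by (smallest label in subtree,
subtree size, serialized form) and the print root minimizes the full string,
so isomorphic trees serialize identically. The canonical string is a
complete invariant and doubles as the general isomorphism test for the small
trees where it is needed.

## The gene-tree distance

For a gene tree T on labels X and a species tree S on Y ⊇ X:

1. restrict S to X;
2. extend: replace each species leaf whose label has multiplicity k > 1 in
   T by an internal vertex fanning to k leaves with that label (S*);
3. differentiate: rename the k copies of each label a to a│1 … a│k in both
   trees ('│' is reserved and rejected in input labels); copies are numbered
   by canonical leaf order, which is one arbitrary choice among the k! —
   the distance is invariant to it (property-tested with randomized
   assignments);
4. return the split-based RF distance of the two singly-labeled trees.

This split route (`rf_multree`) is the package's oracle. The profile score
is its sum over gene trees; gene trees with fewer than 4 leaves are scored
by the same formulas (their split set is simply empty).

### The rooted route

The search needs a distance that updates in O(1) per SPR regraft, which the
split route cannot do. The rooted route (`rf_multree_lca`) roots both
differentiated trees at a shared label — the smallest original gene label of
multiplicity 1, else copy 1 of the smallest label — and computes, bottom-up,
the LCA mapping from the species side into the gene side together with each
species vertex's cluster size restricted to the gene labels (species labels
outside the gene tree map to a null sentinel ξ, so no explicit restriction
is built). The vertex function f counts, for each internal gene vertex, the
species vertices mapping to it with equal restricted cluster size; equal
sizes under an LCA mapping force cluster equality, so f(u) > 0 means u's
cluster is matched.

The distance is then recovered by the counting identity

    RF = 2·|F| + I_S − I_T

with F = {internal gene vertices with f = 0}, I_T the internal gene vertex
count, and I_S the number of species-side internal vertices that survive
restriction to the gene labels (≥ 2 children with nonempty restricted
clusters). When the restricted species side is binary, I_S = |X′| − 2 and
the identity reduces to the classical form |L(T)| − |I(T)| + 2|F| − 2. The
generalized count is necessary here: a multiplicity-k fan with k ≥ 3 is a
polytomy on the species side, and the classical form overcounts in that
case (e.g. gene ((a,a),(a,b)) against any species tree containing a and b:
the split distance is 1, the classical form gives 2). The two routes are
asserted equal, exactly, on hundreds of random instances with
multiplicities up to 3 and missing taxa — this dual-route agreement is the
package's central correctness property.

## The search

**Phase I (greedy leaf addition).** Labels are shuffled by the seeded
generator; the first three form a star, and each subsequent label is tried
on every edge of the partial tree, keeping the attachment minimizing the
profile score restricted to the placed labels (ties: canonical edge order).
The attachment objective is the RF score itself — the only objective in
scope.

**Phase II (steepest descent).** Each iteration scores every SPR move and
takes the best strictly improving neighbor (ties: first in canonical
prune-edge/regraft-edge order); equal-score moves are rejected, so the score
sequence is strictly decreasing and cannot cycle. The search stops at a
local optimum; `restarts` reruns phase I+II with fresh randomization and
keeps the best result. A score of 0 is a global optimum and short-circuits
the remaining work. SPR moves are generated on the singly-labeled species
tree; a species leaf's fan moves with it as a unit, and the fan's internal
structure is never itself pruned.

**Incremental rescoring.** For each pruned subtree, the regrafts are
enumerated by an Euler tour of the remaining subtree, starting at an edge
incident to its canonically smallest leaf, so consecutive regraft edges
share a vertex. Per gene tree: the rooted gene side is static (rooted at a
shared label chosen inside the remaining subtree, cached across prune
edges), and the first regraft is scored from scratch. Each subsequent step
moves the attachment vertex across the shared pivot, so only the attachment
vertex and the pivot can change their restricted cluster — the three
possible parent/child configurations of the pair are handled by recomputing
those at most two vertices from their children. At most four gene-side
vertex-function values change (the old and new mapping targets of the two
vertices), and the score moves by 2|L| − 2|G| where G and L are the gene
vertices whose f left or entered zero. When the pruned or the remaining part
shares no label with a gene tree, that gene's distance is unchanged by every
regraft and the walk is skipped outright.

One caveat the implementation tracks explicitly: with missing taxa (gene
labels a strict subset of the species labels), the surviving-internal count
I_S itself can change by ±1 as the pruned subtree crosses label-free
regions of the tree, adding a ΔI_S term to the update. The pure
2|L| − 2|G| ledger is exact whenever gene and species label sets coincide
(fans included — every fan leaf survives restriction); the instrumented
tests assert the exact ledger on full-coverage instances and the corrected
ledger in general, and every incremental score is asserted equal to a
from-scratch recomputation either way.

Instrumentation (`SearchStats`) counts regraft updates and mapping-entry
writes; the mean mapping updates per regraft is asserted ≤ 8, and total
work is checked to scale linearly in the number of gene trees — the
operational content of the per-iteration Θ(nmk) complexity.

## The simulator

The simulator generates the package's study conditions end to end.

* **Species chronogram**: unit-rate Yule process, tips cut at the time the
  (n+1)-st speciation would occur, all node times rescaled so the
  root-to-tip height is exactly the requested value (default 220 tyrs for
  the 50-taxon scale, 440 for 100 taxa; time units are relative). The
  sampler is checked against the analytic Yule cherry-count expectation
  (n/3) over 500 replicates.
* **Gene birth node**: breadth-first from the root's children, each parent
  edge tested for a Poisson event at rate `birth_rate` (default 1/height,
  about one expected event per root-to-tip path — the rate is a free
  parameter of the design; the fallback when no event fires is the root).
  A fixed 4 genes per profile are born at the root, representing gene
  families sampled across distantly related species.
* **Duplication/loss**: each gene copy evolves independently within each
  species branch as a continuous-time birth-death process (defaults 0.002
  events/gene per tyr for the `dl` and `both` conditions); surviving copies
  enter both daughter branches at speciations; all-loss subtrees are pruned
  and unary vertices suppressed. E[#duplications] = rate × total gene
  lineage length is verified to 3 standard errors. Families with fewer than
  4 surviving leaves are resampled with a derived seed (and the birth node
  redrawn when the family cannot reach 4 leaves at all, e.g. a tip birth
  with zero duplication rate).
* **Lateral transfer**: subtree transfer on the rooted gene tree — the
  subtree at a uniformly chosen vertex is regrafted at a uniformly chosen
  edge with neither endpoint on the root-to-source path and outside the
  moved subtree (0–2 events per gene under `lgt`/`both`); impossible events
  are skipped and logged. The admissible-pair set is tested against a
  brute-force enumeration.
* **Missing data**: a per-gene fraction ~ U(0, 0.25) of leaves deleted
  uniformly at random (the uniform draw is a design choice; a fixed grid
  would also fit the stated range), redrawn if fewer than 4 leaves would
  remain.
* **Estimation error**: optional random NNI moves (default 0). This is a
  deliberate stand-in for sequence simulation and ML gene-tree estimation,
  which are out of scope; it perturbs topology but does not mimic
  alignment-length or rate-heterogeneity effects, so tests that pass under
  NNI noise say nothing about the error structure of real ML trees.

**ATE** (average topological error) is 100·RF/(internal edges of both
trees): 0 for identical topologies, 100 for trees sharing no split; for
two binary trees on n taxa the denominator is 2(n−3).

Everything is driven by a single integer seed per entry point; identical
seeds give byte-identical outputs.

## Scales used in the checked experiments

The automated end-to-end check runs the clean condition at 16 taxa and 25
gene trees with 3 restarts over 20 replicates, recovering the true tree
(score 0, ATE 0) in ≥ 18/20; random-instance suites use ≤ 10 labels,
multiplicities ≤ 3, and ≤ 5 gene trees. These sizes were chosen so the full
suite completes in a couple of minutes on one core while still exercising
fans, missing taxa, and every update case of the incremental scorer; the
search itself has handled the 50-taxon/150-gene scale in informal runs but
no accuracy claims are made at that scale.

## Known limitations

* The distance between two arbitrary mul-trees is NP-complete and is not
  implemented; the package only scores mul-trees against singly-labeled
  species trees.
* The search is a local-search heuristic: no optimality guarantee, and
  tie-breaking (canonical order) and restart policy are package choices
  where the method description is silent.
* Non-binary gene trees are accepted (splits and clusters handle
  polytomies); the dual-route equality is verified for them in tests, but
  the rooted route's classical counting form assumes more structure than a
  polytomous gene tree provides, which is why the generalized identity is
  used throughout.
* Branch lengths are parsed but never used; everything is purely
  topological.
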