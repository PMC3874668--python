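# mulrf

Species-tree inference from **multi-copy gene trees** by minimizing a
generalized Robinson–Foulds (RF) distance.

## The problem

Genome-scale data sets routinely yield gene families with several copies per
species — the product of gene duplication and loss, lateral transfer, deep
coalescence, and plain estimation error. A gene tree from such a family is a
*mul-tree*: an unrooted tree whose leaves are gene copies labeled with
species names, so the same label may appear many times. Most species-tree
methods reconcile gene trees under one specific event model (duplications,
duplication+loss, transfers); this package instead uses a generic topological
distance that is agnostic about the cause of discordance.

## The method

For a profile *P* = (T₁, …, T_k) of mul-trees, find a binary singly-labeled
species tree *S* on the union of the gene labels minimizing

    RF(P, S) = Σᵢ RF(Tᵢ, S)

RF between two arbitrary mul-trees is NP-complete, but the gene-vs-species
case is easy: restrict *S* to the gene's labels, **extend** it by replacing
each species leaf whose label occurs *k* times in the gene tree with a
*k*-leaf fan (giving *S\**), assign the duplicate copies distinct names
consistently in both trees (**full differentiation**), and take the ordinary
split-based RF distance of the two singly-labeled trees. The distance does
not depend on which consistent differentiation is chosen.

The optimization itself is NP-hard, so the search is heuristic:

* **Phase I** — greedy leaf addition in a seeded random order, each label
  attached where the partial profile score is minimized;
* **Phase II** — steepest-descent local search over the SPR (subtree
  prune-and-regraft) neighborhood until no neighbor strictly improves the
  score.

Scoring the neighborhood is fast because regrafts are performed in
Euler-tour order over the remaining subtree: after one full computation per
pruned subtree, each successive regraft updates an LCA mapping and a
vertex-function count at no more than two species-side vertices, changing
the distance by `2|L| − 2|G|` (the clusters lost/gained a match). The
package also ships the gene-family simulator used to exercise the method
(Yule chronograms, duplication/loss, lateral transfer, missing leaves) and
the ATE evaluation metric (normalized RF on a 0–100 scale).

## Worked example

```python
from mulrf import Profile, SpeciesTree, parse_newick, rf_multree, rf_profile

species = SpeciesTree.from_multree(parse_newick("(a,b,(c,d));"))
genes = Profile([
    parse_newick("((a,a),(b,c));"),   # two copies of a, compatible
    parse_newick("((a,b),(a,c));"),   # copies of a split apart: conflict
])
print([rf_multree(g, species) for g in genes])  # [0, 2]
print(rf_profile(genes, species))               # 2
```

The first gene scores 0: its only split, {a,a}|{b,c}, is exactly the fan
split that extending *any* species tree realizes. The second scores 2: a
split separating two copies of the same label can never match the extension,
and one species-side split goes unmatched in return.

Inference, from `examples/02_infer_species_tree.py` (four 8-taxon gene
trees, one with a duplicated leaf, two with conflicting placements):

```text
inferred species tree: ((((a,b),(c,d)),(e,f)),g,h);
final total RF score:  6
```

The score is the summed distance of the gene trees to the inferred tree —
0 for the two genes it displays exactly, 2 + 4 for the two deliberate
conflicts. The `examples/` directory has one short script per capability
(scoring, inference, simulation + ATE evaluation), and the same
functionality is exposed as a command-line tool:

```sh
mulrf simulate --condition dl --n-taxa 16 --k-genes 25 --seed 1 --out-dir sim/
mulrf infer --genes sim/genes.nwk --out sim/estimate.nwk --seed 1 --restarts 3
mulrf score --genes sim/genes.nwk --species sim/estimate.nwk
mulrf ate sim/estimate.nwk truth.nwk
```

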