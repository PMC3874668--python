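import random

import pytest

from mulrf.trees import MulTree, SpeciesTree, parse_newick


def attach_random_leaves(tree: MulTree, labels, rng) -> MulTree:
    for lab in labels:
        edges = tree.edges()
        p, q = edges[rng.randrange(len(edges))]
        w = tree.new_vertex()
        l = tree.new_vertex()
        tree._remove_edge(p, q)
        tree._add_edge(p, w)
        tree._add_edge(w, q)
        tree._add_edge(w, l)
        tree.leaf_labels[l] = lab
    return tree


def random_multree(rng: random.Random, labels, max_mult: int = 3) -> MulTree:
    """Random binary mul-tree: each label receives 1..max_mult copies, then a
    uniform sequential edge-attachment topology."""
    leaves = [lab for lab in labels for _ in range(rng.randint(1, max_mult))]
    rng.shuffle(leaves)
    t = MulTree({0: [1], 1: [0]}, {0: leaves[0], 1: leaves[1]})
    attach_random_leaves(t, leaves[2:], rng)
    t.validate()
    return t


def random_species(rng: random.Random, labels) -> SpeciesTree:
    labs = list(labels)
    rng.shuffle(labs)
    t = MulTree({0: [1], 1: [0]}, {0: labs[0], 1: labs[1]})
    attach_random_leaves(t, labs[2:], rng)
    return SpeciesTree.from_multree(t)


@pytest.fixture
def quartet_ab_cd():
    return SpeciesTree.from_multree(parse_newick("((a,b),(c,d));"))


@pytest.fixture
def quartet_ac_bd():
    return SpeciesTree.from_multree(parse_newick("((a,c),(b,d));"))
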