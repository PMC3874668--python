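"""Generalized Robinson-Foulds distance between multi-copy gene trees and a
singly-labeled species tree.

The RF distance between two arbitrary mul-trees is NP-complete, but the
gene-tree-vs-species-tree case is easy: extend the species tree so its label
multiplicities match the gene tree's (each species leaf whose label occurs k
times in the gene tree becomes a k-leaf fan), give the duplicate leaves
unique names consistently in both trees ("full differentiation"), and take
the plain split-based RF distance of the two resulting singly-labeled trees.
Any consistent differentiation yields the same distance, so the value is
well defined.

Two computation routes are provided:

* :func:`rf_multree` -- the split-set route: restrict, extend, differentiate,
  symmetric difference of split sets.  This is the package's oracle.
* :func:`rf_multree_lca` -- the rooted route via LCA mappings and the vertex
  function, which is what the SPR search updates incrementally.  Extra
  species labels are absorbed by the null sentinel (xi) instead of an
  explicit restriction.

The rooted route uses the generalized identity

    RF = 2 * |F_S| + I_S - I_T

where F_S is the set of internal gene-tree vertices whose cluster matches no
species-side restricted cluster, I_T the internal gene-tree vertex count, and
I_S the number of species-side internal vertices that survive restriction to
the gene labels (>= 2 children with nonempty restricted clusters).  When the
restricted species side is binary, I_S = |L(T)| - 2 and the identity reduces
to the classical form RF = |L(T)| - |I(T)| + 2|F_S| - 2.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .trees import (
    DIFF_SEP,
    MulTree,
    RootedTree,
    SpeciesTree,
    TreeError,
)

__all__ = [
    "Extension",
    "DifferentiationPair",
    "Profile",
    "LcaMapping",
    "VertexFunction",
    "extend_relative",
    "differentiate_consistently",
    "rf_splits",
    "rf_multree",
    "rf_multree_lca",
    "rf_profile",
    "lca_mapping",
    "vertex_function",
    "rf_lemma2",
    "choose_root_label",
]


# ---------------------------------------------------------------------------
# Extension S*
# ---------------------------------------------------------------------------


@dataclass
class Extension:
    """The species tree extended to match a gene tree's label multiplicities.

    Each species leaf whose label has multiplicity k > 1 in the gene tree is
    replaced by an internal vertex fanning out to k leaves with that label.
    """

    extended_tree: MulTree
    fan_map: dict[str, list[int]]
    origin: SpeciesTree
    relative_to: MulTree


def extend_relative(species: SpeciesTree, gene: MulTree) -> Extension:
    missing = gene.label_set - species.label_set
    if missing:
        raise TreeError(
            f"gene labels absent from species tree: {', '.join(sorted(missing))}"
        )
    mult = gene.label_multiset
    # the extension is a mul-tree, not singly labeled
    ext = MulTree(
        {v: list(nb) for v, nb in species.adj.items()}, dict(species.leaf_labels)
    )
    fan_map: dict[str, list[int]] = {}
    leaf_of = {lab: v for v, lab in ext.leaf_labels.items()}
    for lab in sorted(mult):
        k = mult[lab]
        if k <= 1:
            continue
        s = leaf_of[lab]
        del ext.leaf_labels[s]  # s becomes the fan's internal vertex
        fan = []
        for _ in range(k):
            l = ext.new_vertex()
            ext._add_edge(s, l)
            ext.leaf_labels[l] = lab
            fan.append(l)
        fan_map[lab] = fan
    ext.edge_lengths = {}
    # a fan of size 2 replacing an isolated leaf pair can leave a degree-2 hub
    ext._suppress_degree2()
    fan_map = {lab: [v for v in fans if v in ext.adj] for lab, fans in fan_map.items()}
    return Extension(ext, fan_map, species, gene)


# ---------------------------------------------------------------------------
# Consistent full differentiation
# ---------------------------------------------------------------------------


@dataclass
class DifferentiationPair:
    """Consistent singly-labeled relabelings of a gene tree and an extension.

    For every shared label the two trees use the identical set of
    differentiated labels, so split sets are directly comparable.
    """

    gene_diff: MulTree
    species_diff: MulTree
    suffix_map: dict[str, list[str]]


def _differentiated(label: str, i: int) -> str:
    return f"{label}{DIFF_SEP}{i}"


def differentiate_gene(
    gene: MulTree, permutation_seed: Optional[int] = None
) -> tuple[MulTree, dict[str, list[str]]]:
    """Relabel the k copies of each duplicate label a as a|1..a|k.

    Copies are numbered in the canonical leaf order by default; with a
    ``permutation_seed`` the assignment within each label class is shuffled
    (used to exercise the invariance of the distance to the choice).
    """
    mult = gene.label_multiset
    g = gene.copy()
    counters: Counter = Counter()
    order = gene.canonical_leaf_order()
    if permutation_seed is not None:
        rng = random.Random(permutation_seed)
        by_label: dict[str, list[int]] = {}
        for v in order:
            by_label.setdefault(gene.leaf_labels[v], []).append(v)
        order = []
        for lab in sorted(by_label):
            vs = by_label[lab]
            rng.shuffle(vs)
            order.extend(vs)
    suffix_map: dict[str, list[str]] = {}
    for v in order:
        lab = gene.leaf_labels[v]
        if mult[lab] == 1:
            suffix_map.setdefault(lab, [lab])
            continue
        counters[lab] += 1
        new = _differentiated(lab, counters[lab])
        g.leaf_labels[v] = new
        suffix_map.setdefault(lab, []).append(new)
    return g, suffix_map


def differentiate_consistently(
    gene: MulTree, ext: Extension, permutation_seed: Optional[int] = None
) -> DifferentiationPair:
    """Build mutually consistent full differentiations of ``gene`` and ``ext``."""
    mult = gene.label_multiset
    ext_mult = ext.extended_tree.label_multiset
    for lab in gene.label_set:
        if ext_mult.get(lab, 0) != mult[lab]:
            raise TreeError(
                f"label {lab!r}: gene multiplicity {mult[lab]} != "
                f"extension multiplicity {ext_mult.get(lab, 0)}"
            )
    gene_diff, suffix_map = differentiate_gene(gene, permutation_seed)
    sp = ext.extended_tree.copy()
    for lab, fan in ext.fan_map.items():
        for i, v in enumerate(fan, start=1):
            sp.leaf_labels[v] = _differentiated(lab, i)
    return DifferentiationPair(gene_diff, sp, suffix_map)


# ---------------------------------------------------------------------------
# Split-based distance (the oracle)
# ---------------------------------------------------------------------------


def rf_splits(t1: MulTree, t2: MulTree) -> int:
    """RF distance of two singly-labeled trees on the same label set:
    the size of the symmetric difference of their non-trivial split sets."""
    for t in (t1, t2):
        if any(c > 1 for c in t.label_multiset.values()):
            raise TreeError("rf_splits requires singly-labeled trees")
    if t1.label_set != t2.label_set:
        raise TreeError("rf_splits requires identical label sets")
    return len(t1.splits() ^ t2.splits())


def rf_multree(gene: MulTree, species: SpeciesTree) -> int:
    """RF distance between a multi-copy gene tree and a species tree.

    Restricts the species tree to the gene's labels, extends it to match the
    gene's multiplicities, differentiates consistently, and compares split
    sets.  Deterministic and independent of the differentiation choice.
    """
    if gene.size < 2:
        raise TreeError("gene tree must have >= 2 leaves")
    X = gene.label_set
    restricted = species.restrict(X)
    restricted = SpeciesTree(
        {v: list(nb) for v, nb in restricted.adj.items()},
        dict(restricted.leaf_labels),
    )
    ext = extend_relative(restricted, gene)
    pair = differentiate_consistently(gene, ext)
    return rf_splits(pair.gene_diff, pair.species_diff)


@dataclass
class Profile:
    """An ordered collection of input gene trees."""

    gene_trees: list[MulTree]

    def __post_init__(self) -> None:
        if not all(isinstance(t, MulTree) for t in self.gene_trees):
            raise TypeError("Profile expects MulTree instances")

    @property
    def union_labels(self) -> set[str]:
        out: set[str] = set()
        for t in self.gene_trees:
            out |= t.label_set
        return out

    @property
    def sizes(self) -> list[int]:
        return [t.size for t in self.gene_trees]

    def __len__(self) -> int:
        return len(self.gene_trees)

    def __iter__(self):
        return iter(self.gene_trees)


def rf_profile(profile: Profile, species: SpeciesTree) -> int:
    """Total RF distance from a profile to a species tree (sum over genes)."""
    missing = profile.union_labels - species.label_set
    if missing:
        raise TreeError(
            f"species tree is missing gene labels: {', '.join(sorted(missing))}"
        )
    return sum(rf_multree(g, species) for g in profile)


# ---------------------------------------------------------------------------
# Rooted machinery: LCA mapping, vertex function, the counting identity
# ---------------------------------------------------------------------------


#: Sentinel for species-side vertices whose restricted cluster is empty.
XI = None


@dataclass
class LcaMapping:
    """LCA mapping from a rooted species-side tree to a rooted gene-side tree.

    ``mapping[v]`` is the gene-tree vertex that is the least common ancestor
    of the leaves in v's cluster restricted to the gene labels, or ``None``
    (the sentinel xi) when that restriction is empty.
    ``restricted_cluster_sizes[v]`` is the size of the restricted cluster.
    ``surviving_internal`` counts the species-side internal vertices that
    would remain internal after restriction to the gene labels.
    """

    mapping: dict[int, Optional[int]]
    restricted_cluster_sizes: dict[int, int]
    surviving_internal: int


def lca_mapping(
    species_rooted: RootedTree,
    gene_rooted: RootedTree,
    gene_labels: set[str],
) -> LcaMapping:
    """Bottom-up LCA mapping from the species side to the gene side."""
    g_leaf = gene_rooted.leaf_by_label()
    mapping: dict[int, Optional[int]] = {}
    sizes: dict[int, int] = {}
    surviving = 0
    for v in species_rooted.postorder():
        if v in species_rooted.leaf_labels:
            lab = species_rooted.leaf_labels[v]
            if lab in gene_labels:
                if lab not in g_leaf:
                    raise TreeError(f"gene tree lacks a leaf labeled {lab!r}")
                mapping[v] = g_leaf[lab]
                sizes[v] = 1
            else:
                mapping[v] = XI
                sizes[v] = 0
        else:
            acc: Optional[int] = XI
            size = 0
            nonempty = 0
            for w in species_rooted.children[v]:
                size += sizes[w]
                if sizes[w] > 0:
                    nonempty += 1
                    acc = mapping[w] if acc is XI else gene_rooted.lca(acc, mapping[w])
            mapping[v] = acc
            sizes[v] = size
            if v != species_rooted.root and nonempty >= 2:
                surviving += 1
    return LcaMapping(mapping, sizes, surviving)


@dataclass
class VertexFunction:
    """The vertex function f: counts, per internal gene-tree vertex, the
    species-side vertices whose restricted cluster equals its cluster."""

    f: dict[int, int]
    zero_count: int
    surviving_internal: int


def vertex_function(
    lmap: LcaMapping, gene_rooted: RootedTree, species_rooted: RootedTree
) -> VertexFunction:
    g_sizes = gene_rooted.cluster_sizes
    gene_internal = set(gene_rooted.internal_vertices)
    f = {u: 0 for u in gene_internal}
    for v in species_rooted.internal_vertices:
        u = lmap.mapping[v]
        if u is not XI and u in gene_internal and g_sizes[u] == lmap.restricted_cluster_sizes[v]:
            f[u] += 1
    zero = sum(1 for u in gene_internal if f[u] == 0)
    return VertexFunction(f, zero, lmap.surviving_internal)


def rf_lemma2(vf: VertexFunction, gene_rooted: RootedTree) -> int:
    """RF distance from the vertex function: 2|F_S| + I_S - I_T.

    Equals |L(T)| - |I(T)| + 2|F_S| - 2 whenever the restricted species side
    is binary (then I_S = |L(T)| - 2); the generalized count stays correct
    when multiplicity fans of size >= 3 make the species side non-binary.
    """
    i_t = len(gene_rooted.internal_vertices)
    return 2 * vf.zero_count + vf.surviving_internal - i_t


def choose_root_label(
    gene_diff: MulTree, suffix_map: dict[str, list[str]]
) -> str:
    """Deterministic rooting label: the lexicographically smallest original
    gene label with multiplicity one, else copy 1 of the smallest label."""
    singles = sorted(lab for lab, names in suffix_map.items() if len(names) == 1)
    if singles:
        return singles[0]
    lab = min(suffix_map)
    return _differentiated(lab, 1)


def rf_multree_lca(gene: MulTree, species: SpeciesTree) -> int:
    """RF distance via the rooted LCA machinery (no explicit restriction).

    Builds the extension of the full species tree relative to the gene tree,
    differentiates consistently, roots both trees at a shared label, and
    applies the counting identity.  Species labels outside the gene tree are
    absorbed by the xi sentinel.  Must agree exactly with :func:`rf_multree`.
    """
    if gene.size < 2:
        raise TreeError("gene tree must have >= 2 leaves")
    ext = extend_relative(species, gene)
    pair = differentiate_consistently(gene, ext)
    r = choose_root_label(pair.gene_diff, pair.suffix_map)
    g_rooted = pair.gene_diff.root_at_leaf(r)
    s_rooted = pair.species_diff.root_at_leaf(r)
    lmap = lca_mapping(s_rooted, g_rooted, set(pair.gene_diff.leaf_labels.values()))
    vf = vertex_function(lmap, g_rooted, s_rooted)
    return rf_lemma2(vf, g_rooted)
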