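"""Unrooted multi-labeled trees (mul-trees) and their structural operations.

A mul-tree is an unrooted tree whose leaves carry labels via a surjective
labeling map, so several leaves may share a label -- the natural shape of a
multi-copy gene tree, where each leaf is one gene copy tagged with the species
it was sampled from.  A species tree is the singly-labeled special case.

This module provides the containers (:class:`MulTree`, :class:`SpeciesTree`,
:class:`RootedTree`, :class:`Split`), Newick reading/writing with duplicate
labels and polytomies allowed, and the structural operations everything else
is built on: restriction to a label subset, edge contraction, vertex
refinement, split enumeration, and rooting at a leaf.

Conventions
-----------
* Branch lengths and internal node labels are parsed (and branch lengths
  retained from parsing) but ignored by every distance computation.
* Degree-2 vertices arising anywhere (rooted inputs, restriction, leaf
  deletion) are suppressed immediately, so the invariant "every internal
  vertex has degree >= 3" always holds.
* Splits are the bipartitions of the leaf-label multiset induced by internal
  edges only; pendant (trivial) splits are never included.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "TreeError",
    "NewickError",
    "Split",
    "MulTree",
    "SpeciesTree",
    "RootedTree",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
]

#: Reserved separator used to mint unique labels when differentiating
#: duplicate leaf labels; forbidden in input labels.
DIFF_SEP = "│"


class TreeError(ValueError):
    """A structural precondition on a tree operation was violated."""


class NewickError(ValueError):
    """Malformed Newick input; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _part_key(counts: Counter) -> tuple:
    return tuple(sorted(counts.items()))


@dataclass(frozen=True)
class Split:
    """A bipartition of a tree's leaf-label multiset induced by an internal edge.

    Parts are multisets stored as sorted ``(label, count)`` tuples; the two
    parts are kept in sorted order so equal splits compare equal regardless of
    orientation.
    """

    part_a: tuple
    part_b: tuple

    @classmethod
    def of(cls, side_a: Counter, side_b: Counter) -> "Split":
        a, b = sorted((_part_key(side_a), _part_key(side_b)))
        return cls(a, b)

    @property
    def canonical_key(self) -> tuple:
        return (self.part_a, self.part_b)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        fmt = lambda p: ",".join(l if c == 1 else f"{l}x{c}" for l, c in p)
        return f"{{{fmt(self.part_a)}}}|{{{fmt(self.part_b)}}}"


class MulTree:
    """An unrooted tree with a surjective leaf-labeling map.

    Vertices are opaque integer ids; ``adj`` maps each vertex to the list of
    its neighbors, and ``leaf_labels`` maps each leaf vertex to its label.
    """

    __slots__ = ("adj", "leaf_labels", "edge_lengths", "_next_id")

    def __init__(
        self,
        adj: dict[int, list[int]],
        leaf_labels: dict[int, str],
        edge_lengths: Optional[dict[frozenset, float]] = None,
    ):
        self.adj = adj
        self.leaf_labels = leaf_labels
        self.edge_lengths = edge_lengths or {}
        self._next_id = max(adj, default=-1) + 1

    # -- basic accessors ---------------------------------------------------

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    @property
    def vertices(self) -> list[int]:
        return list(self.adj)

    @property
    def leaves(self) -> list[int]:
        return [v for v in self.adj if v in self.leaf_labels]

    @property
    def internal_vertices(self) -> list[int]:
        return [v for v in self.adj if v not in self.leaf_labels]

    @property
    def size(self) -> int:
        """Number of leaves |T|."""
        return len(self.leaf_labels)

    @property
    def label_set(self) -> set[str]:
        return set(self.leaf_labels.values())

    @property
    def label_multiset(self) -> Counter:
        return Counter(self.leaf_labels.values())

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u not in self.leaf_labels and v not in self.leaf_labels
        ]

    @property
    def is_binary(self) -> bool:
        return all(len(self.adj[v]) == 3 for v in self.internal_vertices)

    def new_vertex(self) -> int:
        v = self._next_id
        self._next_id += 1
        self.adj[v] = []
        return v

    def copy(self) -> "MulTree":
        t = self.__class__.__new__(self.__class__)
        t.adj = {v: list(nb) for v, nb in self.adj.items()}
        t.leaf_labels = dict(self.leaf_labels)
        t.edge_lengths = dict(self.edge_lengths)
        t._next_id = self._next_id
        return t

    # -- validation --------------------------------------------------------

    def validate(self, min_leaves: int = 1) -> None:
        n_edges = sum(len(nb) for nb in self.adj.values()) // 2
        if n_edges != len(self.adj) - 1:
            raise TreeError("not a tree: |E| != |V| - 1")
        if self.adj and not self._connected():
            raise TreeError("not a tree: graph is disconnected")
        for v, nb in self.adj.items():
            if v in self.leaf_labels:
                if len(nb) > 1:
                    raise TreeError(f"leaf vertex {v} has degree {len(nb)}")
            elif len(nb) < 3 and len(self.adj) > 2:
                raise TreeError(f"internal vertex {v} has degree {len(nb)} < 3")
        if self.size < min_leaves:
            raise TreeError(f"tree has {self.size} leaves; need >= {min_leaves}")

    def _connected(self) -> bool:
        start = next(iter(self.adj))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in self.adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(self.adj)

    # -- internal mutation helpers (callers work on copies) ----------------

    def _add_edge(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def _remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def _suppress_degree2(self) -> None:
        """Splice out every degree-2 non-leaf vertex and drop degree-0/1 stubs."""
        changed = True
        while changed:
            changed = False
            for v in list(self.adj):
                if v in self.leaf_labels:
                    continue
                deg = len(self.adj[v])
                if deg == 2:
                    a, b = self.adj[v]
                    self._remove_edge(v, a)
                    self._remove_edge(v, b)
                    del self.adj[v]
                    if a != b:
                        self._add_edge(a, b)
                    changed = True
                elif deg <= 1 and len(self.adj) > 1:
                    for nb in list(self.adj[v]):
                        self._remove_edge(v, nb)
                    del self.adj[v]
                    changed = True

    def remove_leaves(self, leaf_vertices: Iterable[int]) -> "MulTree":
        """Return a copy with the given leaf vertices deleted and the tree re-normalized."""
        t = self.copy()
        for v in leaf_vertices:
            if v not in t.leaf_labels:
                raise TreeError(f"vertex {v} is not a leaf")
            for nb in list(t.adj[v]):
                t._remove_edge(v, nb)
            del t.adj[v]
            del t.leaf_labels[v]
        t.edge_lengths = {}
        t._suppress_degree2()
        return t

    # -- structural operations --------------------------------------------

    def restrict(self, labels: Iterable[str]) -> "MulTree":
        """Restriction T|U: minimal subtree spanning leaves labeled in U,
        degree-2 vertices suppressed."""
        keep = set(labels) & self.label_set
        if not keep:
            raise TreeError("restriction label set does not intersect the tree's labels")
        drop = [v for v, lab in self.leaf_labels.items() if lab not in keep]
        return self.remove_leaves(drop)

    def contract_edge(self, edge: tuple[int, int]) -> "MulTree":
        """Collapse an internal edge, identifying its endpoints."""
        u, v = edge
        if u in self.leaf_labels or v in self.leaf_labels:
            raise TreeError("cannot contract a pendant edge")
        if v not in self.adj.get(u, ()):
            raise TreeError(f"no edge {edge} in tree")
        t = self.copy()
        t._remove_edge(u, v)
        for nb in list(t.adj[v]):
            t._remove_edge(v, nb)
            t._add_edge(u, nb)
        del t.adj[v]
        t.edge_lengths = {}
        return t

    def refine_vertex(
        self, vertex: int, cell: Iterable[int]
    ) -> "MulTree":
        """Refine an unresolved vertex by pulling the neighbors in ``cell``
        onto a new vertex joined to ``vertex`` by a fresh internal edge.

        ``cell`` is one side of the neighbor partition; the rest of the
        neighbors stay on ``vertex``.  Both cells must have >= 2 members.
        """
        if vertex in self.leaf_labels:
            raise TreeError("cannot refine a leaf")
        nbs = set(self.adj[vertex])
        cell = set(cell)
        if not cell <= nbs:
            raise TreeError("partition cell is not a subset of the vertex's neighbors")
        other = nbs - cell
        if len(nbs) <= 3:
            raise TreeError("vertex is already resolved (degree <= 3)")
        if len(cell) < 2 or len(other) < 2:
            raise TreeError("both partition cells must have >= 2 members")
        t = self.copy()
        w = t.new_vertex()
        for nb in cell:
            t._remove_edge(vertex, nb)
            t._add_edge(w, nb)
        t._add_edge(vertex, w)
        t.edge_lengths = {}
        return t

    def splits(self) -> frozenset:
        """The split set Sigma(T): one bipartition per internal edge."""
        out = set()
        for u, v in self.internal_edges():
            side = self._labels_on_side(u, v)
            other = self.label_multiset - side
            out.add(Split.of(side, other))
        return frozenset(out)

    def _labels_on_side(self, away_from: int, start: int) -> Counter:
        """Leaf-label multiset of the component of ``start`` when the edge
        {away_from, start} is removed."""
        seen = {away_from, start}
        stack = [start]
        counts: Counter = Counter()
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                counts[self.leaf_labels[x]] += 1
            for w in self.adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return counts

    def component_vertices(self, away_from: int, start: int) -> set[int]:
        """Vertices of the component of ``start`` after removing the edge
        {away_from, start} (``start`` included)."""
        seen = {away_from, start}
        stack = [start]
        while stack:
            x = stack.pop()
            for w in self.adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        seen.discard(away_from)
        return seen

    def root_at_leaf(self, label: str) -> "RootedTree":
        """Root the tree by subdividing the pendant edge of the unique leaf
        carrying ``label``; that leaf stays a leaf child of the new root."""
        hits = [v for v, lab in self.leaf_labels.items() if lab == label]
        if not hits:
            raise TreeError(f"rooting label {label!r} absent from tree")
        if len(hits) > 1:
            raise TreeError(f"rooting label {label!r} has multiplicity {len(hits)}")
        leaf = hits[0]
        if not self.adj[leaf]:
            raise TreeError("cannot root a single-vertex tree")
        nb = self.adj[leaf][0]
        root = max(self.adj) + 1
        parent: dict[int, Optional[int]] = {root: None, leaf: root}
        children: dict[int, list[int]] = {root: [leaf, nb], leaf: []}
        order = [nb]
        parent[nb] = root
        # iterative orientation away from the root
        queue = [(nb, leaf)]
        while queue:
            v, frm = queue.pop()
            kids = [w for w in self.adj[v] if w != frm and not (v == nb and w == leaf)]
            children[v] = kids
            for w in kids:
                parent[w] = v
                queue.append((w, v))
        return RootedTree(root, parent, children, dict(self.leaf_labels))

    # -- canonical serialization and isomorphism ---------------------------

    def canonical_newick(self) -> str:
        """Deterministic Newick string: identical for isomorphic trees.

        Children are ordered by (smallest label in subtree, subtree leaf
        count, canonical substring); the print root minimizing the full
        string is chosen among internal vertices.
        """
        if not self.adj:
            raise TreeError("empty tree")
        if self.size == 1:
            (lab,) = self.leaf_labels.values()
            return f"{lab};"

        def sub(v: int, frm: int) -> tuple[str, int, str]:
            if v in self.leaf_labels:
                lab = self.leaf_labels[v]
                return (lab, 1, lab)
            parts = sorted(sub(w, v) for w in self.adj[v] if w != frm)
            minlab = min(p[0] for p in parts)
            nl = sum(p[1] for p in parts)
            return (minlab, nl, "(" + ",".join(p[2] for p in parts) + ")")

        roots = self.internal_vertices
        if not roots:  # two-leaf tree
            labs = sorted(self.leaf_labels.values())
            return "(" + ",".join(labs) + ");"
        best = None
        for r in roots:
            parts = sorted(sub(w, r) for w in self.adj[r])
            s = "(" + ",".join(p[2] for p in parts) + ");"
            if best is None or s < best:
                best = s
        return best

    def canonical_leaf_order(self) -> list[int]:
        """Leaf vertices in the pre-order of the canonical serialization."""
        if self.size <= 1:
            return list(self.leaf_labels)

        def sub(v: int, frm: Optional[int]) -> tuple[tuple, list[int]]:
            if v in self.leaf_labels:
                lab = self.leaf_labels[v]
                return ((lab, 1, lab), [v])
            parts = sorted(
                (sub(w, v) for w in self.adj[v] if w != frm), key=lambda p: p[0]
            )
            minlab = min(p[0][0] for p in parts)
            nl = sum(p[0][1] for p in parts)
            key = (minlab, nl, "(" + ",".join(p[0][2] for p in parts) + ")")
            order = [v for p in parts for v in p[1]]
            return (key, order)

        roots = self.internal_vertices
        if not roots:
            return sorted(self.leaf_labels, key=lambda v: self.leaf_labels[v])
        best = None
        for r in roots:
            parts = sorted((sub(w, r) for w in self.adj[r]), key=lambda p: p[0])
            s = "(" + ",".join(p[0][2] for p in parts) + ");"
            order = [v for p in parts for v in p[1]]
            if best is None or s < best[0]:
                best = (s, order)
        return best[1]

    def is_isomorphic(self, other: "MulTree") -> bool:
        """Exact labeled-tree isomorphism via canonical-form equality.

        Intended for small trees (the canonical form is a complete invariant);
        use :meth:`SpeciesTree.same_topology` for singly-labeled comparisons.
        """
        return self.canonical_newick() == other.canonical_newick()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.__class__.__name__} {self.canonical_newick()}>"


class SpeciesTree(MulTree):
    """A singly-labeled mul-tree: the labeling map is a bijection."""

    def validate(self, min_leaves: int = 1) -> None:
        super().validate(min_leaves=min_leaves)
        counts = self.label_multiset
        dups = sorted(l for l, c in counts.items() if c > 1)
        if dups:
            raise TreeError(f"species tree has duplicate labels: {', '.join(dups)}")

    @classmethod
    def from_multree(cls, tree: MulTree) -> "SpeciesTree":
        t = cls(
            {v: list(nb) for v, nb in tree.adj.items()},
            dict(tree.leaf_labels),
            dict(tree.edge_lengths),
        )
        t.validate()
        return t

    def same_topology(self, other: "SpeciesTree") -> bool:
        """Topological identity of singly-labeled trees on the same label set.

        By the splits-equivalence property of singly-labeled trees, equality
        of split sets is equivalent to isomorphism.
        """
        if self.label_set != other.label_set:
            raise TreeError("trees are on different label sets")
        return self.splits() == other.splits()


@dataclass
class RootedTree:
    """Rooted view of a tree: parent/children maps plus leaf-cluster data.

    ``clusters`` maps each vertex to the multiset (as a frozenset of
    ``(label, count)`` pairs) of leaf labels in its subtree; ``cluster_sizes``
    gives the corresponding leaf counts.  Built lazily on first access.
    """

    root: int
    parent: dict[int, Optional[int]]
    children: dict[int, list[int]]
    leaf_labels: dict[int, str]
    _clusters: Optional[dict[int, frozenset]] = field(default=None, repr=False)
    _cluster_sizes: Optional[dict[int, int]] = field(default=None, repr=False)
    _postorder: Optional[list[int]] = field(default=None, repr=False)
    _depth: Optional[dict[int, int]] = field(default=None, repr=False)
    _up: Optional[list[dict[int, int]]] = field(default=None, repr=False)

    @property
    def vertices(self) -> list[int]:
        return list(self.children)

    @property
    def internal_vertices(self) -> list[int]:
        """Internal vertices I(T): everything but the root and the leaves."""
        return [
            v for v in self.children if v != self.root and v not in self.leaf_labels
        ]

    def postorder(self) -> list[int]:
        if self._postorder is None:
            out: list[int] = []
            stack = [(self.root, False)]
            while stack:
                v, done = stack.pop()
                if done:
                    out.append(v)
                else:
                    stack.append((v, True))
                    for w in self.children[v]:
                        stack.append((w, False))
            self._postorder = out
        return self._postorder

    def _build_clusters(self) -> None:
        clusters: dict[int, Counter] = {}
        sizes: dict[int, int] = {}
        for v in self.postorder():
            if v in self.leaf_labels:
                clusters[v] = Counter({self.leaf_labels[v]: 1})
                sizes[v] = 1
            else:
                c: Counter = Counter()
                for w in self.children[v]:
                    c += clusters[w]
                clusters[v] = c
                sizes[v] = sum(c.values())
        self._clusters = {v: frozenset(c.items()) for v, c in clusters.items()}
        self._cluster_sizes = sizes

    @property
    def clusters(self) -> dict[int, frozenset]:
        if self._clusters is None:
            self._build_clusters()
        return self._clusters

    @property
    def cluster_sizes(self) -> dict[int, int]:
        if self._cluster_sizes is None:
            self._build_clusters()
        return self._cluster_sizes

    def leaf_by_label(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v, lab in self.leaf_labels.items():
            out.setdefault(lab, v)
        return out

    # -- LCA queries via binary lifting ------------------------------------

    def _build_lca(self) -> None:
        depth = {self.root: 0}
        for v in reversed(self.postorder()):
            if v != self.root:
                depth[v] = depth[self.parent[v]] + 1
        up0 = {v: (self.parent[v] if self.parent[v] is not None else v)
               for v in self.children}
        levels = [up0]
        max_d = max(depth.values(), default=0)
        while (1 << len(levels)) <= max_d:
            prev = levels[-1]
            levels.append({v: prev[prev[v]] for v in prev})
        self._depth = depth
        self._up = levels

    def lca(self, u: int, v: int) -> int:
        if self._up is None:
            self._build_lca()
        depth, up = self._depth, self._up
        if depth[u] < depth[v]:
            u, v = v, u
        diff = depth[u] - depth[v]
        k = 0
        while diff:
            if diff & 1:
                u = up[k][u]
            diff >>= 1
            k += 1
        if u == v:
            return u
        for k in range(len(up) - 1, -1, -1):
            if up[k][u] != up[k][v]:
                u, v = up[k][u], up[k][v]
        return self.parent[u]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_UNQUOTED_OK = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.|-"
)


def parse_newick(text: str, allow_duplicates: bool = True) -> MulTree:
    """Parse a single Newick statement into a :class:`MulTree`.

    Duplicate leaf labels and polytomies are allowed (``allow_duplicates``
    controls the former).  Branch lengths and internal labels are read and
    dropped from the topology; a rooted (two-child top level) Newick is read
    as its unrooted underlying tree, with the degree-2 root suppressed.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def peek() -> str:
        skip_ws()
        if pos >= n:
            raise NewickError("unexpected end of input", pos)
        return text[pos]

    def read_label() -> str:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            start = pos
            pos += 1
            out = []
            while True:
                if pos >= n:
                    raise NewickError("unterminated quoted label", start)
                ch = text[pos]
                if ch == "'":
                    if pos + 1 < n and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(ch)
                pos += 1
        start = pos
        while pos < n and text[pos] in _UNQUOTED_OK:
            pos += 1
        return text[start:pos]

    def read_length() -> None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (text[pos] in "+-eE." or text[pos].isdigit()):
                pos += 1
            if start == pos:
                raise NewickError("expected branch length after ':'", pos)
            try:
                float(text[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None

    tree = MulTree({}, {})

    def subtree() -> int:
        nonlocal pos
        ch = peek()
        if ch == "(":
            pos += 1
            v = tree.new_vertex()
            while True:
                child = subtree()
                tree._add_edge(v, child)
                ch = peek()
                if ch == ",":
                    pos += 1
                    continue
                if ch == ")":
                    pos += 1
                    break
                raise NewickError(f"expected ',' or ')', found {ch!r}", pos)
            read_label()  # internal label, discarded
            read_length()
            return v
        lab = read_label()
        if not lab:
            raise NewickError("expected a leaf label", pos)
        if DIFF_SEP in lab:
            raise NewickError(f"label contains reserved character {DIFF_SEP!r}", pos)
        read_length()
        v = tree.new_vertex()
        tree.leaf_labels[v] = lab
        return v

    skip_ws()
    if pos >= n:
        raise NewickError("empty input", pos)
    top = subtree()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickError("expected ';' terminating the tree", pos)
    pos += 1
    skip_ws()
    if pos < n:
        raise NewickError("trailing characters after ';'", pos)

    tree._suppress_degree2()
    if top in tree.adj and top not in tree.leaf_labels and len(tree.adj[top]) in (1, 2):
        tree._suppress_degree2()
    tree.validate(min_leaves=2)
    if not allow_duplicates:
        dups = sorted(l for l, c in tree.label_multiset.items() if c > 1)
        if dups:
            raise NewickError(f"duplicate leaf labels: {', '.join(dups)}", 0)
    return tree


def write_newick(tree: MulTree) -> str:
    """Canonical Newick serialization (see :meth:`MulTree.canonical_newick`)."""
    return tree.canonical_newick()


def read_newick_file(path, allow_duplicates: bool = True) -> list[MulTree]:
    """Read a Newick file, one tree per line; '#'-prefixed lines are comments."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append(parse_newick(line, allow_duplicates=allow_duplicates))
            except (NewickError, TreeError) as exc:
                raise NewickError(f"line {lineno}: {exc}", 0) from exc
    return out


def write_newick_file(path, trees: Sequence[MulTree]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")
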