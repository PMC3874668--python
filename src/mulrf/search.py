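"""SPR local search for the minimum-total-RF species tree.

The heuristic runs in two phases.  Phase I builds an initial species tree by
greedy leaf addition: start from three randomly chosen labels, then insert
the remaining labels one at a time (in a seeded random order) at the
attachment edge minimizing the RF score of the partial tree against the
profile restricted to the placed labels.  Phase II is steepest-descent local
search over the SPR (subtree prune and regraft) neighborhood: each iteration
scores every neighbor and moves to the best one, stopping when no neighbor
strictly improves the score.

Scoring the whole neighborhood naively costs a full RF computation per
neighbor.  Instead, for each pruned subtree the regrafts are performed in
Euler-tour order over the remaining subtree, so consecutive regraft edges
are adjacent and the rooted RF machinery (LCA mapping + vertex function) can
be patched in O(1) per step: only the attachment vertex and the pivot vertex
shared by consecutive edges change their clusters, so at most four
gene-tree vertices change their vertex-function value, and the distance
changes by 2|L| - 2|G| (plus a suppression correction when the gene tree
misses species labels; see docs/methods.md).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .trees import DIFF_SEP, MulTree, RootedTree, SpeciesTree, TreeError
from .rf import (
    Profile,
    differentiate_gene,
    rf_multree,
    rf_profile,
)

__all__ = [
    "SprMove",
    "SearchConfig",
    "SearchTrace",
    "SearchStats",
    "UpdateDelta",
    "spr_apply",
    "spr_neighborhood",
    "regraft_order",
    "score_neighborhood",
    "spr_search_step",
    "greedy_init",
    "attach_leaf",
    "infer",
]


def _norm(edge: Sequence[int]) -> tuple[int, int]:
    a, b = edge
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SprMove:
    """One subtree-prune-regraft move on a binary species tree.

    ``prune_edge`` is the cut edge; ``pruned_side`` names the endpoint whose
    subtree is pruned; ``regraft_edge`` is an edge of the remaining subtree
    (in original vertex ids; the edge created by suppressing the old
    attachment vertex is named by its surviving endpoints).
    """

    prune_edge: tuple[int, int]
    pruned_side: int
    regraft_edge: tuple[int, int]


@dataclass
class SearchConfig:
    seed: int = 0
    max_iterations: int = 1000
    restarts: int = 1
    initial_tree: Optional[SpeciesTree] = None

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class UpdateDelta:
    """Bookkeeping for one incremental regraft update of one gene tree."""

    changed: frozenset
    gained: frozenset
    lost: frozenset
    delta_surviving: int
    rf_before: int
    rf_after: int
    mapping_updates: int


class SearchStats:
    """Instrumentation counters for the incremental neighborhood scorer."""

    def __init__(self, collect_deltas: bool = False):
        self.collect_deltas = collect_deltas
        self.deltas: list[UpdateDelta] = []
        self.regraft_updates = 0
        self.mapping_entry_updates = 0
        self.initial_builds = 0
        self.prune_directions = 0
        self.skipped_gene_walks = 0

    @property
    def mean_mapping_updates_per_regraft(self) -> float:
        if self.regraft_updates == 0:
            return 0.0
        return self.mapping_entry_updates / self.regraft_updates


@dataclass
class SearchTrace:
    """Per-iteration scores and counters for one inference run."""

    scores: list[int] = field(default_factory=list)
    moves: list[Optional[SprMove]] = field(default_factory=list)
    counters: dict = field(default_factory=dict)
    restart_scores: list[int] = field(default_factory=list)

    @property
    def final_score(self) -> int:
        return self.scores[-1]


# ---------------------------------------------------------------------------
# SPR moves and neighborhoods
# ---------------------------------------------------------------------------


def _remaining_adjacency(
    species: SpeciesTree, keep: int, pruned: int
) -> Optional[dict[int, list[int]]]:
    """Adjacency of the remaining subtree after cutting {keep, pruned} and
    pruning the ``pruned`` side; the degree-2 cut endpoint is spliced out.
    Returns None when nothing remains to regraft onto."""
    comp = species.component_vertices(away_from=pruned, start=keep)
    if len(comp) < 3:
        return None  # a single vertex (or nothing) remains
    adj = {v: [w for w in species.adj[v] if w in comp] for v in comp}
    nbs = adj[keep]
    if len(nbs) == 2:  # internal cut endpoint: splice
        a, b = nbs
        adj[a].remove(keep)
        adj[b].remove(keep)
        adj[a].append(b)
        adj[b].append(a)
        del adj[keep]
    return adj


def _prune_directions(species: SpeciesTree) -> Iterator[tuple[tuple[int, int], int, dict]]:
    for edge in sorted(_norm(e) for e in species.edges()):
        for pruned in edge:
            keep = edge[0] if pruned == edge[1] else edge[1]
            rem = _remaining_adjacency(species, keep, pruned)
            if rem is not None:
                yield edge, pruned, rem


def regraft_order(rem_adj: dict[int, list[int]], start: int) -> list[tuple[int, int]]:
    """Euler-tour edge ordering of the remaining subtree, starting at a leaf.

    Each edge appears at most twice; consecutive distinct edges share a
    vertex; the k-th regraft is performed on the k-th edge of the sequence.
    """
    if len(rem_adj[start]) != 1:
        raise TreeError("regraft walk must start at a leaf")
    walk = [start]

    def dfs(u: int, frm: Optional[int]) -> None:
        for w in sorted(rem_adj[u]):
            if w == frm:
                continue
            walk.append(w)
            dfs(w, u)
            walk.append(u)

    dfs(start, None)
    return list(zip(walk, walk[1:]))


def _walk_start(species: SpeciesTree, rem_adj: dict[int, list[int]]) -> int:
    leaves = [v for v in rem_adj if len(rem_adj[v]) == 1]
    return min(leaves, key=lambda v: (species.leaf_labels.get(v, ""), v))


def spr_apply(species: SpeciesTree, move: SprMove) -> SpeciesTree:
    """Apply one SPR move, returning a new binary species tree."""
    eu, ev = move.prune_edge
    if ev not in species.adj.get(eu, ()):
        raise TreeError(f"prune edge {move.prune_edge} not in tree")
    pruned = move.pruned_side
    keep = eu if pruned == ev else ev
    rem = _remaining_adjacency(species, keep, pruned)
    if rem is None:
        raise TreeError("nothing remains to regraft onto")
    p, q = move.regraft_edge
    if p not in rem or q not in rem.get(p, ()):
        raise TreeError(f"regraft edge {move.regraft_edge} is not in the remaining subtree")
    t = species.copy()
    t.edge_lengths = {}
    t._remove_edge(keep, pruned)
    if len(t.adj[keep]) == 2:
        a, b = t.adj[keep]
        t._remove_edge(keep, a)
        t._remove_edge(keep, b)
        del t.adj[keep]
        t._add_edge(a, b)
    w = t.new_vertex()
    t._remove_edge(p, q)
    t._add_edge(p, w)
    t._add_edge(w, q)
    t._add_edge(w, pruned)
    t.validate()
    return t


def spr_neighborhood(species: SpeciesTree) -> list[SpeciesTree]:
    """All distinct trees reachable by one SPR move (the input excluded)."""
    if species.size < 4:
        return []
    own = species.splits()
    seen = {own}
    out = []
    for edge, pruned, rem in _prune_directions(species):
        keep = edge[0] if pruned == edge[1] else edge[1]
        for re in sorted({_norm((u, v)) for u in rem for v in rem[u]}):
            t = spr_apply(species, SprMove(edge, pruned, re))
            key = t.splits()
            if key not in seen:
                seen.add(key)
                out.append(t)
    return out


# ---------------------------------------------------------------------------
# Incremental neighborhood scoring
# ---------------------------------------------------------------------------


class _GeneContext:
    """Per-gene precomputation shared across prune directions."""

    def __init__(self, gene: MulTree):
        self.gene = gene
        self.labels = gene.label_set
        self.mult = gene.label_multiset
        self.gene_diff, self.suffix_map = differentiate_gene(gene)
        self.diff_labels = set(self.gene_diff.leaf_labels.values())
        self._rooted: dict[str, RootedTree] = {}

    def rooted(self, root_label: str) -> RootedTree:
        rt = self._rooted.get(root_label)
        if rt is None:
            rt = self.gene_diff.root_at_leaf(root_label)
            rt.cluster_sizes  # force bottom-up pass
            self._rooted[root_label] = rt
        return rt


def _diff_name(label: str, i: int) -> str:
    return f"{label}{DIFF_SEP}{i}"


class _WalkScorer:
    """Scores every regraft of one pruned subtree against one gene tree.

    Maintains the rooted, extended, differentiated species-side tree with its
    LCA mapping into the (static) rooted gene tree, the vertex-function
    counts, and the count of species-side internal vertices surviving
    restriction; each step of the Euler walk patches at most two species-side
    vertices.
    """

    def __init__(
        self,
        ctx: _GeneContext,
        species: SpeciesTree,
        rem_adj: dict[int, list[int]],
        y_root: int,
        y_vertices: set[int],
        walk: list[tuple[int, int]],
        stats: Optional[SearchStats] = None,
    ):
        self.ctx = ctx
        self.stats = stats
        self.y_child = y_root
        X = ctx.labels
        mult = ctx.mult

        # rooting label: smallest shared species label in the remaining part
        shared_x = sorted(
            species.leaf_labels[v]
            for v in rem_adj
            if v in species.leaf_labels and species.leaf_labels[v] in X
        )
        a = shared_x[0]
        root_label = a if mult[a] == 1 else _diff_name(a, 1)
        self.g = ctx.rooted(root_label)
        self.g_internal = set(self.g.internal_vertices)
        self.g_csize = self.g.cluster_sizes
        self.g_leaf = self.g.leaf_by_label()
        self.i_t = len(self.g_internal)

        # --- build the unrooted extended species-side structure -----------
        U: dict[int, list[int]] = {v: list(ws) for v, ws in rem_adj.items()}
        for v in y_vertices:
            U[v] = [w for w in species.adj[v] if w in y_vertices]
        next_id = max(species.adj) + 1
        leaf_diff: dict[int, Optional[str]] = {}
        for v in list(U):
            lab = species.leaf_labels.get(v)
            if lab is None:
                continue
            if lab in X and mult[lab] > 1:
                for i in range(1, mult[lab] + 1):
                    w = next_id
                    next_id += 1
                    U[v].append(w)
                    U[w] = [v]
                    leaf_diff[w] = _diff_name(lab, i)
            elif lab in X:
                leaf_diff[v] = lab
            else:
                leaf_diff[v] = None  # maps to the xi sentinel
        # attachment vertex on the first walk edge, carrying the pruned part
        att = next_id
        next_id += 1
        p0, q0 = walk[0]
        U[p0].remove(q0)
        U[q0].remove(p0)
        U[att] = [p0, q0, y_root]
        U[p0].append(att)
        U[q0].append(att)
        U[y_root].append(att)
        # root above the leaf carrying root_label
        rleaf = next(v for v, lab in leaf_diff.items() if lab == root_label)
        root = next_id
        nb = U[rleaf][0]
        U[rleaf] = [root]
        U[nb].remove(rleaf)
        U[nb].append(root)
        U[root] = [rleaf, nb]
        self.att, self.root, self.rleaf = att, root, rleaf
        self.is_leaf = set(leaf_diff)

        # orient away from the root
        parent: dict[int, Optional[int]] = {root: None}
        children: dict[int, list[int]] = {}
        stack = [(root, None)]
        order = []
        while stack:
            v, frm = stack.pop()
            kids = [w for w in U[v] if w != frm]
            children[v] = kids
            order.append(v)
            for w in kids:
                parent[w] = v
                stack.append((w, v))
        self.parent, self.children = parent, children

        # bottom-up restricted sizes, LCA mapping, vertex-function counts
        msize: dict[int, int] = {}
        mmap: dict[int, Optional[int]] = {}
        f = {u: 0 for u in self.g_internal}
        contrib: dict[int, Optional[int]] = {}
        alive: dict[int, int] = {}
        i_s = 0
        for v in reversed(order):
            if v in self.is_leaf:
                lab = leaf_diff[v]
                if lab is None:
                    msize[v], mmap[v] = 0, None
                else:
                    msize[v], mmap[v] = 1, self.g_leaf[lab]
                continue
            size = 0
            acc: Optional[int] = None
            nonempty = 0
            for w in children[v]:
                size += msize[w]
                if msize[w] > 0:
                    nonempty += 1
                    acc = mmap[w] if acc is None else self.g.lca(acc, mmap[w])
            msize[v], mmap[v] = size, acc
            if v == root:
                continue
            u = acc
            c = (
                u
                if u is not None and u in self.g_internal and self.g_csize[u] == size
                else None
            )
            contrib[v] = c
            if c is not None:
                f[c] += 1
            alive[v] = 1 if nonempty >= 2 else 0
            i_s += alive[v]
        self.msize, self.mmap, self.f = msize, mmap, f
        self.contrib, self.alive = contrib, alive
        self.i_s = i_s
        self.zero_f = sum(1 for u in self.g_internal if f[u] == 0)
        if stats is not None:
            stats.initial_builds += 1

    @property
    def rf(self) -> int:
        return 2 * self.zero_f + self.i_s - self.i_t

    # -- incremental update -------------------------------------------------

    def _recompute(self, v: int, touched: dict) -> int:
        """Recompute msize/mmap/contribution of internal vertex v from its
        children; returns the number of mapping entries written."""
        size = 0
        acc: Optional[int] = None
        nonempty = 0
        for w in self.children[v]:
            size += self.msize[w]
            if self.msize[w] > 0:
                nonempty += 1
                acc = self.mmap[w] if acc is None else self.g.lca(acc, self.mmap[w])
        self.msize[v], self.mmap[v] = size, acc
        old_c = self.contrib[v]
        new_c = (
            acc
            if acc is not None and acc in self.g_internal and self.g_csize[acc] == size
            else None
        )
        if old_c != new_c:
            if old_c is not None:
                if old_c not in touched:
                    touched[old_c] = self.f[old_c]
                self.f[old_c] -= 1
                if self.f[old_c] == 0:
                    self.zero_f += 1
            if new_c is not None:
                if new_c not in touched:
                    touched[new_c] = self.f[new_c]
                self.f[new_c] += 1
                if self.f[new_c] == 1:
                    self.zero_f -= 1
            self.contrib[v] = new_c
        new_alive = 1 if nonempty >= 2 else 0
        d_alive = new_alive - self.alive[v]
        self.alive[v] = new_alive
        self.i_s += d_alive
        return 1

    def move_to(self, edge: tuple[int, int], prev: tuple[int, int]) -> None:
        """Move the attachment vertex from ``prev`` to the adjacent ``edge``."""
        if set(edge) == set(prev):
            if self.stats is not None:
                self.stats.regraft_updates += 1
            return
        pivot = (set(edge) & set(prev)).pop()
        att, root, rleaf = self.att, self.root, self.rleaf
        parent, children = self.parent, self.children

        rf_before = self.rf
        touched: dict[int, int] = {}
        i_s_before = self.i_s

        # detach the attachment vertex
        p = parent[att]
        kids = children[att]
        c = kids[0] if kids[1] == self.y_child else kids[1]
        pk = children[p]
        pk[pk.index(att)] = c
        parent[c] = p
        # insert into the target edge
        a, b = edge
        if parent.get(b) == a:
            lo, hi = b, a
        elif parent.get(a) == b:
            lo, hi = a, b
        else:  # the root subdivides this pendant edge
            lo = b if a == rleaf else a
            hi = root
        hk = children[hi]
        hk[hk.index(lo)] = att
        parent[att] = hi
        children[att] = [lo, self.y_child]
        parent[lo] = att

        updates = 0
        if parent[att] == pivot:
            updates += self._recompute(att, touched)
            if pivot != root:
                updates += self._recompute(pivot, touched)
        else:
            if pivot != root and pivot not in self.is_leaf:
                updates += self._recompute(pivot, touched)
            updates += self._recompute(att, touched)

        if self.stats is not None:
            self.stats.regraft_updates += 1
            self.stats.mapping_entry_updates += updates
            if self.stats.collect_deltas:
                changed = frozenset(u for u, old in touched.items() if self.f[u] != old)
                gained = frozenset(
                    u for u, old in touched.items() if old == 0 and self.f[u] >= 1
                )
                lost = frozenset(
                    u for u, old in touched.items() if old >= 1 and self.f[u] == 0
                )
                self.stats.deltas.append(
                    UpdateDelta(
                        changed,
                        gained,
                        lost,
                        self.i_s - i_s_before,
                        rf_before,
                        self.rf,
                        updates,
                    )
                )

    def run(self, walk: list[tuple[int, int]]) -> dict[tuple[int, int], int]:
        """Scores for every distinct regraft edge of the walk."""
        scores = {_norm(walk[0]): self.rf}
        for prev, cur in zip(walk, walk[1:]):
            self.move_to(cur, prev)
            scores.setdefault(_norm(cur), self.rf)
        return scores


def score_neighborhood(
    profile: Profile,
    species: SpeciesTree,
    stats: Optional[SearchStats] = None,
) -> list[tuple[SprMove, int]]:
    """Total profile score for every SPR move of the species tree.

    Moves that reproduce the input tree (regrafts adjacent to the original
    attachment) are included and score the current value.  Every entry
    equals a from-scratch ``rf_profile`` of the realized neighbor.
    """
    missing = profile.union_labels - species.label_set
    if missing:
        raise TreeError(
            f"species tree is missing gene labels: {', '.join(sorted(missing))}"
        )
    if species.size < 4:
        return []
    ctxs = [_GeneContext(g) for g in profile]
    base = [rf_multree(g, species) for g in profile]
    results: list[tuple[SprMove, int]] = []
    for edge, pruned, rem in _prune_directions(species):
        if stats is not None:
            stats.prune_directions += 1
        keep = edge[0] if pruned == edge[1] else edge[1]
        y_vertices = species.component_vertices(away_from=keep, start=pruned)
        y_labels = {
            species.leaf_labels[v] for v in y_vertices if v in species.leaf_labels
        }
        x_labels = {
            species.leaf_labels[v] for v in rem if v in species.leaf_labels
        }
        start = _walk_start(species, rem)
        walk = regraft_order(rem, start)
        totals: dict[tuple[int, int], int] = {}
        edge_order: list[tuple[int, int]] = []
        for e in walk:
            ne = _norm(e)
            if ne not in totals:
                totals[ne] = 0
                edge_order.append(ne)
        for i, ctx in enumerate(ctxs):
            if not (ctx.labels & x_labels) or not (ctx.labels & y_labels):
                # the pruned or remaining part shares no label with this
                # gene: its distance is unchanged by any regraft
                if stats is not None:
                    stats.skipped_gene_walks += 1
                for ne in edge_order:
                    totals[ne] += base[i]
                continue
            scorer = _WalkScorer(ctx, species, rem, pruned, y_vertices, walk, stats)
            gene_scores = scorer.run(walk)
            for ne in edge_order:
                totals[ne] += gene_scores[ne]
        for ne in edge_order:
            results.append((SprMove(edge, pruned, ne), totals[ne]))
    return results


def spr_search_step(
    profile: Profile, species: SpeciesTree, stats: Optional[SearchStats] = None
) -> SpeciesTree:
    """One steepest-descent step: the best SPR neighbor, or the input tree
    when no neighbor is strictly better."""
    tree, _, _, _ = _search_step(profile, species, stats)
    return tree


def _search_step(
    profile: Profile, species: SpeciesTree, stats: Optional[SearchStats] = None
) -> tuple[SpeciesTree, int, int, Optional[SprMove]]:
    current = rf_profile(profile, species)
    best_move: Optional[SprMove] = None
    best_score = current
    for move, score in score_neighborhood(profile, species, stats):
        if score < best_score:
            best_move, best_score = move, score
    if best_move is None:
        return species, current, current, None
    return spr_apply(species, best_move), best_score, current, best_move


# ---------------------------------------------------------------------------
# Phase I: greedy leaf addition
# ---------------------------------------------------------------------------


def attach_leaf(tree: SpeciesTree, edge: tuple[int, int], label: str) -> SpeciesTree:
    """New species tree with ``label`` attached by subdividing ``edge``."""
    p, q = edge
    if q not in tree.adj.get(p, ()):
        raise TreeError(f"no edge {edge} in tree")
    t = tree.copy()
    t.edge_lengths = {}
    w = t.new_vertex()
    leaf = t.new_vertex()
    t._remove_edge(p, q)
    t._add_edge(p, w)
    t._add_edge(w, q)
    t._add_edge(w, leaf)
    t.leaf_labels[leaf] = label
    return t


def greedy_init(profile: Profile, seed: int) -> SpeciesTree:
    """Phase-I starting tree: greedy leaf adding in a seeded random order.

    Each label is attached at the edge minimizing the RF score of the
    partial tree against the profile restricted to the labels placed so far;
    ties are broken by canonical edge order.
    """
    labels = sorted(profile.union_labels)
    if len(labels) < 3:
        raise TreeError("need at least 3 distinct labels to build a species tree")
    rng = random.Random(seed)
    rng.shuffle(labels)
    a, b, c = labels[:3]
    tree = SpeciesTree({0: [1, 2, 3], 1: [0], 2: [0], 3: [0]},
                       {1: a, 2: b, 3: c})
    for lab in labels[3:]:
        placed = tree.label_set | {lab}
        restricted = []
        for g in profile:
            inter = g.label_set & placed
            if len(inter) < 2:
                continue
            rg = g.restrict(inter)
            if rg.size >= 2:
                restricted.append(rg)
        best = None
        best_score = None
        for e in sorted(_norm(x) for x in tree.edges()):
            cand = attach_leaf(tree, e, lab)
            s = sum(rf_multree(rg, cand) for rg in restricted)
            if best_score is None or s < best_score:
                best, best_score = cand, s
        tree = best
    return tree


# ---------------------------------------------------------------------------
# Phase II driver
# ---------------------------------------------------------------------------


def infer(
    profile: Profile, config: Optional[SearchConfig] = None
) -> tuple[SpeciesTree, SearchTrace]:
    """Infer a species tree minimizing the total RF distance to the profile.

    Runs greedy initialization followed by steepest-descent SPR iterations
    until no neighbor strictly improves the score; with ``restarts > 1`` the
    best result over independently initialized runs is returned.  Fully
    deterministic given the profile and the seed.
    """
    config = config or SearchConfig()
    if not profile.gene_trees:
        raise TreeError("empty profile")
    rng = random.Random(config.seed)
    stats = SearchStats()
    best: Optional[tuple[SpeciesTree, list[int], list[Optional[SprMove]]]] = None
    restart_scores: list[int] = []
    for r in range(config.restarts):
        if config.initial_tree is not None and r == 0:
            tree = config.initial_tree
            missing = profile.union_labels - tree.label_set
            if missing:
                raise TreeError(
                    f"initial tree is missing labels: {', '.join(sorted(missing))}"
                )
        else:
            tree = greedy_init(profile, rng.randrange(2**31))
        scores = [rf_profile(profile, tree)]
        moves: list[Optional[SprMove]] = []
        it = 0
        while scores[-1] > 0 and it < config.max_iterations:
            nxt, nscore, cur, move = _search_step(profile, tree, stats)
            if move is None or nscore >= cur:
                break
            tree, it = nxt, it + 1
            scores.append(nscore)
            moves.append(move)
        restart_scores.append(scores[-1])
        if best is None or scores[-1] < best[1][-1]:
            best = (tree, scores, moves)
        if best[1][-1] == 0:
            break  # a zero score is globally optimal
    tree, scores, moves = best
    trace = SearchTrace(
        scores=scores,
        moves=moves,
        counters={
            "n_labels": len(profile.union_labels),
            "k_genes": len(profile),
            "regraft_updates": stats.regraft_updates,
            "mapping_entry_updates": stats.mapping_entry_updates,
            "initial_builds": stats.initial_builds,
            "prune_directions": stats.prune_directions,
            "skipped_gene_walks": stats.skipped_gene_walks,
        },
        restart_scores=restart_scores,
    )
    return tree, trace
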