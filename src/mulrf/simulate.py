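"""Gene-tree simulation and the average-topological-error (ATE) metric.

The simulator provides fully synthetic study inputs so the inference method
can be exercised without external data.  The pipeline mirrors the standard
way multi-copy gene families are generated for species-tree benchmarks:

1. an ultrametric species chronogram from a Yule (pure-birth) process,
   rescaled to a requested height in time units (tyrs);
2. a gene birth node per gene family, sampled by testing a Poisson process
   along the branches in breadth-first order from the root's children (a
   fixed number of genes per profile are born at the root itself);
3. birth-death evolution of the gene lineage within the species tree:
   each gene copy independently duplicates and is lost at constant rates per
   tyr, and every surviving copy enters both daughter branches at each
   speciation -- producing a multi-labeled gene tree;
4. optional lateral transfers (subtree prune-and-regraft on the rooted gene
   tree, the regraft edge constrained away from the root-to-source path);
5. random deletion of a fraction of leaves (missing data);
6. optional random NNI moves emulating gene-tree estimation error (a
   deliberate stand-in for sequence simulation + ML inference, which this
   package does not perform).

ATE is the normalized RF distance between two singly-labeled trees on a
0-100 scale: 100 * RF / (#internal edges of both trees).  0 means identical;
100 means no shared split.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .trees import MulTree, SpeciesTree, TreeError
from .rf import Profile, rf_splits

__all__ = [
    "ChronoTree",
    "DlParams",
    "SimCondition",
    "GeneSimResult",
    "SimulatedProfile",
    "yule_species_tree",
    "sample_gene_birth",
    "evolve_dl",
    "apply_lgt",
    "delete_leaves",
    "perturb_nni",
    "simulate_profile",
    "ate",
]


# ---------------------------------------------------------------------------
# Species chronograms
# ---------------------------------------------------------------------------


@dataclass
class ChronoTree:
    """Rooted ultrametric species tree with branch durations in tyrs.

    ``parent``/``children`` give the topology; ``length[v]`` is the duration
    of the branch above ``v`` (0 for the root); ``tip_labels`` names the
    extant species.
    """

    root: int
    parent: dict[int, Optional[int]]
    children: dict[int, list[int]]
    length: dict[int, float]
    tip_labels: dict[int, str]

    @property
    def height(self) -> float:
        v = next(iter(self.tip_labels))
        h = 0.0
        while v != self.root:
            h += self.length[v]
            v = self.parent[v]
        return h

    def depths(self) -> dict[int, float]:
        out = {self.root: 0.0}
        stack = list(self.children[self.root])
        while stack:
            v = stack.pop()
            out[v] = out[self.parent[v]] + self.length[v]
            stack.extend(self.children[v])
        return out

    def n_tips_below(self, v: int) -> int:
        count = 0
        stack = [v]
        while stack:
            u = stack.pop()
            if not self.children[u]:
                count += 1
            stack.extend(self.children[u])
        return count

    def to_species_tree(self) -> SpeciesTree:
        """The unrooted topology as a :class:`SpeciesTree` (durations dropped)."""
        adj: dict[int, list[int]] = {v: [] for v in self.children}
        for v, p in self.parent.items():
            if p is not None:
                adj[v].append(p)
                adj[p].append(v)
        t = MulTree(adj, dict(self.tip_labels))
        t._suppress_degree2()
        return SpeciesTree({v: list(nb) for v, nb in t.adj.items()},
                           dict(t.leaf_labels))

    def newick(self) -> str:
        def sub(v: int) -> str:
            if v in self.tip_labels:
                return f"{self.tip_labels[v]}:{self.length[v]:.6g}"
            inner = ",".join(sub(w) for w in self.children[v])
            if v == self.root:
                return f"({inner})"
            return f"({inner}):{self.length[v]:.6g}"

        return sub(self.root) + ";"


def yule_species_tree(n_taxa: int, height: float, seed: int) -> ChronoTree:
    """Pure-birth (Yule) chronogram on ``n_taxa`` tips, rescaled so every
    root-to-tip path equals ``height``."""
    if n_taxa < 2:
        raise TreeError("need n_taxa >= 2")
    if height <= 0:
        raise TreeError("height must be positive")
    rng = random.Random(seed)
    # speciation times of a unit-rate Yule process; tips cut at the time the
    # (n+1)-st speciation would occur
    t = 0.0
    split_times = [0.0]  # root split
    lineages = 2
    while lineages < n_taxa:
        t += rng.expovariate(lineages)
        split_times.append(t)
        lineages += 1
    t_end = t + rng.expovariate(lineages)
    scale = height / t_end

    # build topology: each speciation splits a uniformly chosen open lineage
    next_id = 0

    def new(parent_id, t0):
        nonlocal next_id
        v = next_id
        next_id += 1
        return {"id": v, "parent": parent_id, "t0": t0}

    root = new(None, 0.0)
    open_lineages = [new(root["id"], 0.0), new(root["id"], 0.0)]
    records = [root] + open_lineages
    for st in split_times[1:]:
        i = rng.randrange(len(open_lineages))
        node = open_lineages.pop(i)
        node["t1"] = st
        kids = [new(node["id"], st), new(node["id"], st)]
        records.extend(kids)
        open_lineages.extend(kids)
    for node in open_lineages:
        node["t1"] = t_end

    parent: dict[int, Optional[int]] = {}
    children: dict[int, list[int]] = {}
    length: dict[int, float] = {}
    tip_labels: dict[int, str] = {}
    by_id = {r["id"]: r for r in records}
    for r in records:
        v = r["id"]
        parent[v] = r["parent"]
        children.setdefault(v, [])
        if r["parent"] is not None:
            children.setdefault(r["parent"], []).append(v)
            length[v] = (r.get("t1", t_end) - r["t0"]) * scale
        else:
            length[v] = 0.0
    width = len(str(n_taxa))
    tip_ids = sorted(v for v in children if not children[v])
    for i, v in enumerate(tip_ids, start=1):
        tip_labels[v] = f"s{i:0{width}d}"
    return ChronoTree(root["id"], parent, children, length, tip_labels)


def sample_gene_birth(tree: ChronoTree, rate: float, seed: int) -> int:
    """Sample a gene birth node by testing a Poisson process on each parent
    edge in breadth-first order from the root's children; the first edge on
    which an event fires makes its child node the birth node.  Falls back to
    the root when no event fires anywhere."""
    if rate < 0:
        raise TreeError("rate must be >= 0")
    rng = random.Random(seed)
    queue = list(tree.children[tree.root])
    i = 0
    while i < len(queue):
        v = queue[i]
        i += 1
        p_event = 1.0 - math.exp(-rate * tree.length[v]) if rate > 0 else 0.0
        if rng.random() < p_event:
            return v
        queue.extend(tree.children[v])
    return tree.root


# ---------------------------------------------------------------------------
# Gene evolution within the species tree
# ---------------------------------------------------------------------------


@dataclass
class DlParams:
    """Duplication and loss rates, in events per gene lineage per tyr."""

    dup_rate: float = 0.0
    loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise TreeError("rates must be >= 0")


@dataclass
class SimCondition:
    """One of the four study scenarios: none, dl, lgt, both."""

    name: str
    dl_params: DlParams = field(default_factory=DlParams)
    lgt_count_max: int = 0
    deletion_max: float = 0.25
    noise_moves: int = 0

    PRESETS = ("none", "dl", "lgt", "both")

    @classmethod
    def preset(
        cls,
        name: str,
        dup_loss_rate: float = 0.002,
        lgt_count_max: int = 2,
        deletion_max: float = 0.25,
        noise_moves: int = 0,
    ) -> "SimCondition":
        if name not in cls.PRESETS:
            raise TreeError(f"unknown condition {name!r}; expected one of {cls.PRESETS}")
        dl = DlParams(dup_loss_rate, dup_loss_rate) if name in ("dl", "both") else DlParams()
        lgt = lgt_count_max if name in ("lgt", "both") else 0
        return cls(name, dl, lgt, deletion_max, noise_moves)


class _RootedGene:
    """Mutable rooted gene tree used during simulation."""

    __slots__ = ("root", "children", "labels", "_next")

    def __init__(self):
        self.root = None
        self.children: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    def new(self, label: Optional[str] = None) -> int:
        v = self._next
        self._next += 1
        self.children[v] = []
        if label is not None:
            self.labels[v] = label
        return v

    def parent_map(self) -> dict[int, Optional[int]]:
        par: dict[int, Optional[int]] = {self.root: None}
        for v, kids in self.children.items():
            for w in kids:
                par[w] = v
        return par

    def suppress_unary(self) -> None:
        """Remove pass-through vertices and re-root past unary roots."""
        par = self.parent_map()
        for v in list(self.children):
            if v in self.labels or v not in self.children:
                continue
            while len(self.children[v]) == 1 and v != self.root:
                (w,) = self.children[v]
                p = par[v]
                self.children[p][self.children[p].index(v)] = w
                par[w] = p
                del self.children[v]
                v = w
        while self.root is not None and len(self.children[self.root]) == 1 \
                and self.root not in self.labels:
            (w,) = self.children[self.root]
            del self.children[self.root]
            self.root = w

    def to_multree(self) -> MulTree:
        adj: dict[int, list[int]] = {v: [] for v in self.children}
        for v, kids in self.children.items():
            for w in kids:
                adj[v].append(w)
                adj[w].append(v)
        t = MulTree(adj, dict(self.labels))
        t._suppress_degree2()
        return t

    def copy(self) -> "_RootedGene":
        g = _RootedGene()
        g.root = self.root
        g.children = {v: list(k) for v, k in self.children.items()}
        g.labels = dict(self.labels)
        g._next = self._next
        return g


@dataclass
class GeneSimResult:
    """One simulated gene family: the mul-tree plus its event bookkeeping."""

    gene_tree: MulTree
    rooted: Optional[_RootedGene]
    birth_node: int
    n_duplications: int = 0
    n_losses: int = 0
    n_transfers: int = 0
    n_transfers_skipped: int = 0
    n_deleted_leaves: int = 0
    total_branch_length: float = 0.0
    resamples: int = 0


def evolve_dl(
    tree: ChronoTree, birth: int, params: DlParams, seed: int
) -> GeneSimResult:
    """Evolve one gene family inside the species chronogram.

    A single gene lineage starts at the ``birth`` vertex; within each species
    branch every copy independently undergoes duplication/loss as a
    continuous-time birth-death process, and each surviving copy enters both
    daughter branches at speciations.  Copies surviving to the species tips
    become leaves labeled with the species name.  Families ending with fewer
    than 4 leaves are resampled with a derived seed (counted in
    ``resamples``).
    """
    if birth not in tree.children:
        raise TreeError(f"birth vertex {birth} is not in the species tree")
    lam, mu = params.dup_rate, params.loss_rate
    total = lam + mu
    attempt = 0
    while True:
        rng = random.Random(seed + 0x9E3779B1 * attempt)
        g = _RootedGene()
        stats = {"dup": 0, "loss": 0, "length": 0.0}

        def in_branch(sp_v: int, remaining: float) -> Optional[int]:
            """One gene copy traversing the remainder of a species branch."""
            while True:
                dt = rng.expovariate(total) if total > 0 else math.inf
                if dt >= remaining:
                    stats["length"] += remaining
                    return at_node(sp_v)
                stats["length"] += dt
                remaining -= dt
                if rng.random() < (lam / total):
                    stats["dup"] += 1
                    v = g.new()
                    for _ in range(2):
                        child = in_branch(sp_v, remaining)
                        if child is not None:
                            g.children[v].append(child)
                    if not g.children[v]:
                        del g.children[v]
                        return None
                    return v
                stats["loss"] += 1
                return None

        def at_node(sp_v: int) -> Optional[int]:
            kids = tree.children[sp_v]
            if not kids:  # species tip: a surviving gene copy
                return g.new(tree.tip_labels[sp_v])
            v = g.new()
            for w in kids:
                child = in_branch(w, tree.length[w])
                if child is not None:
                    g.children[v].append(child)
            if not g.children[v]:
                del g.children[v]
                return None
            return v

        g.root = at_node(birth)
        if g.root is not None:
            g.suppress_unary()
        n_leaves = len(g.labels)
        if g.root is not None and n_leaves >= 4:
            return GeneSimResult(
                gene_tree=g.to_multree(),
                rooted=g,
                birth_node=birth,
                n_duplications=stats["dup"],
                n_losses=stats["loss"],
                total_branch_length=stats["length"],
                resamples=attempt,
            )
        attempt += 1
        if attempt > 200:
            raise TreeError(
                "gene family resampling did not produce >= 4 surviving leaves; "
                "loss rate too high for this species tree"
            )


# ---------------------------------------------------------------------------
# Lateral transfer, leaf deletion, NNI noise
# ---------------------------------------------------------------------------


def _lgt_candidates(g: _RootedGene) -> dict[int, list[tuple[int, int]]]:
    """Admissible (source vertex c -> regraft edges) map for one transfer.

    The subtree rooted at c is pruned and regrafted at an edge (a, b) such
    that neither a nor b lies on the root-to-c path and the edge is outside
    the pruned subtree.
    """
    par = g.parent_map()
    out: dict[int, list[tuple[int, int]]] = {}
    all_edges = [(v, w) for v, kids in g.children.items() for w in kids]
    for c in g.children:
        if c == g.root:
            continue
        path = set()
        v = c
        while v is not None:
            path.add(v)
            v = par[v]
        sub = set()
        stack = [c]
        while stack:
            v = stack.pop()
            sub.add(v)
            stack.extend(g.children[v])
        edges = [
            (a, b)
            for a, b in all_edges
            if a not in path and b not in path and a not in sub and b not in sub
        ]
        if edges:
            out[c] = edges
    return out


def apply_lgt(result: GeneSimResult, n_events: int, seed: int) -> GeneSimResult:
    """Apply ``n_events`` sequential lateral transfers to the rooted gene tree.

    Each event picks the transferred subtree uniformly among vertices with at
    least one admissible regraft edge, then the edge uniformly; events with
    no admissible pair are skipped and counted."""
    if n_events < 0:
        raise TreeError("n_events must be >= 0")
    if result.rooted is None:
        raise TreeError("lateral transfer requires the rooted gene tree")
    rng = random.Random(seed)
    g = result.rooted.copy()
    applied = skipped = 0
    for _ in range(n_events):
        cands = _lgt_candidates(g)
        if not cands:
            skipped += 1
            continue
        c = rng.choice(sorted(cands))
        a, b = rng.choice(cands[c])
        par = g.parent_map()
        p = par[c]
        g.children[p].remove(c)
        v = g.new()
        g.children[a][g.children[a].index(b)] = v
        g.children[v] = [b, c]
        g.suppress_unary()
        applied += 1
    out = GeneSimResult(
        gene_tree=g.to_multree(),
        rooted=g,
        birth_node=result.birth_node,
        n_duplications=result.n_duplications,
        n_losses=result.n_losses,
        n_transfers=result.n_transfers + applied,
        n_transfers_skipped=result.n_transfers_skipped + skipped,
        n_deleted_leaves=result.n_deleted_leaves,
        total_branch_length=result.total_branch_length,
        resamples=result.resamples,
    )
    return out


def delete_leaves(
    result: GeneSimResult, max_fraction: float, seed: int
) -> GeneSimResult:
    """Delete a random fraction ~ U(0, max_fraction) of leaves (rounded down),
    redrawing the fraction when fewer than 4 leaves would remain."""
    if not (0 <= max_fraction < 1):
        raise TreeError("max_fraction must be in [0, 1)")
    t = result.gene_tree
    rng = random.Random(seed)
    n = t.size
    if max_fraction == 0 or n <= 4:
        return result
    for _ in range(1000):
        k = int(rng.uniform(0.0, max_fraction) * n)
        if n - k >= 4:
            break
    else:
        k = max(0, n - 4)
    if k == 0:
        return result
    victims = rng.sample(sorted(t.leaf_labels), k)
    pruned = t.remove_leaves(victims)
    return GeneSimResult(
        gene_tree=pruned,
        rooted=None,  # rooted bookkeeping is stale after deletion
        birth_node=result.birth_node,
        n_duplications=result.n_duplications,
        n_losses=result.n_losses,
        n_transfers=result.n_transfers,
        n_transfers_skipped=result.n_transfers_skipped,
        n_deleted_leaves=result.n_deleted_leaves + k,
        total_branch_length=result.total_branch_length,
        resamples=result.resamples,
    )


def perturb_nni(result: GeneSimResult, n_moves: int, seed: int) -> GeneSimResult:
    """Apply random nearest-neighbor interchanges: a stand-in for gene-tree
    estimation error, with the move count as the error dial."""
    if n_moves < 0:
        raise TreeError("n_moves must be >= 0")
    rng = random.Random(seed)
    t = result.gene_tree
    for _ in range(n_moves):
        internal = t.internal_edges()
        if not internal:
            break
        u, v = rng.choice(sorted(internal))
        su = rng.choice(sorted(w for w in t.adj[u] if w != v))
        sv = rng.choice(sorted(w for w in t.adj[v] if w != u))
        t = t.copy()
        t._remove_edge(u, su)
        t._remove_edge(v, sv)
        t._add_edge(u, sv)
        t._add_edge(v, su)
        t.edge_lengths = {}
    if t is result.gene_tree:
        return result
    return GeneSimResult(
        gene_tree=t,
        rooted=None,
        birth_node=result.birth_node,
        n_duplications=result.n_duplications,
        n_losses=result.n_losses,
        n_transfers=result.n_transfers,
        n_transfers_skipped=result.n_transfers_skipped,
        n_deleted_leaves=result.n_deleted_leaves,
        total_branch_length=result.total_branch_length,
        resamples=result.resamples,
    )


# ---------------------------------------------------------------------------
# Whole-profile simulation
# ---------------------------------------------------------------------------

#: Number of gene families forced to be born at the species root, emulating
#: sampling of genes present across all distantly related species.
ROOT_BORN_GENES = 4


@dataclass
class SimulatedProfile:
    """A simulated study instance: the true chronogram, the gene profile,
    and the per-gene event records."""

    chrono: ChronoTree
    true_tree: SpeciesTree
    profile: Profile
    records: list[GeneSimResult]


def simulate_profile(
    condition: SimCondition,
    n_taxa: int,
    height: float,
    k_genes: int,
    birth_rate: Optional[float] = None,
    seed: int = 0,
) -> SimulatedProfile:
    """Simulate a species tree and a profile of ``k_genes`` gene trees.

    The first :data:`ROOT_BORN_GENES` genes are born at the species root;
    the rest draw their birth node along the tree.  ``birth_rate`` defaults
    to 1/height (about one expected event per root-to-tip path).
    """
    if k_genes < ROOT_BORN_GENES:
        raise TreeError(f"k_genes must be >= {ROOT_BORN_GENES}")
    rng = random.Random(seed)
    chrono = yule_species_tree(n_taxa, height, rng.randrange(2**31))
    if birth_rate is None:
        birth_rate = 1.0 / height
    records = []
    genes = []
    for i in range(k_genes):
        if i < ROOT_BORN_GENES:
            birth = chrono.root
        else:
            birth = sample_gene_birth(chrono, birth_rate, rng.randrange(2**31))
        while True:
            if (
                i >= ROOT_BORN_GENES
                and condition.dl_params.dup_rate == 0
                and chrono.n_tips_below(birth) < 4
            ):
                birth = sample_gene_birth(chrono, birth_rate, rng.randrange(2**31))
                continue
            try:
                res = evolve_dl(
                    chrono, birth, condition.dl_params, rng.randrange(2**31)
                )
                break
            except TreeError:
                if i < ROOT_BORN_GENES:
                    raise  # root-born family: rates are genuinely too lossy
                birth = sample_gene_birth(chrono, birth_rate, rng.randrange(2**31))
        if condition.lgt_count_max > 0:
            n_ev = rng.randint(0, condition.lgt_count_max)
            res = apply_lgt(res, n_ev, rng.randrange(2**31))
        if condition.deletion_max > 0:
            res = delete_leaves(res, condition.deletion_max, rng.randrange(2**31))
        if condition.noise_moves > 0:
            res = perturb_nni(res, condition.noise_moves, rng.randrange(2**31))
        records.append(res)
        genes.append(res.gene_tree)
    return SimulatedProfile(
        chrono=chrono,
        true_tree=chrono.to_species_tree(),
        profile=Profile(genes),
        records=records,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def ate(true_tree: SpeciesTree, estimated: SpeciesTree) -> float:
    """Average topological error between two singly-labeled trees:
    100 * RF / (#internal edges of both trees).  0 = identical topology,
    100 = no shared split."""
    if true_tree.label_set != estimated.label_set:
        raise TreeError("ATE requires identical label sets")
    denom = len(true_tree.internal_edges()) + len(estimated.internal_edges())
    if denom == 0:
        return 0.0
    return 100.0 * rf_splits(true_tree, estimated) / denom
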