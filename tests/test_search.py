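"""SPR moves, neighborhood enumeration, incremental rescoring, greedy
initialization, and the full two-phase search."""

import random

import pytest

from mulrf.rf import Profile, rf_profile
from mulrf.search import (
    SearchConfig,
    SearchStats,
    SprMove,
    _prune_directions,
    attach_leaf,
    greedy_init,
    infer,
    regraft_order,
    score_neighborhood,
    spr_apply,
    spr_neighborhood,
    spr_search_step,
)
from mulrf.trees import SpeciesTree, TreeError, parse_newick, write_newick

from conftest import random_multree, random_species


def species(s: str) -> SpeciesTree:
    return SpeciesTree.from_multree(parse_newick(s))


def random_instance(rng, n_min=4, n_max=10, k_max=5, full_coverage=False):
    n = rng.randint(n_min, n_max)
    labels = list("abcdefghij"[:n])
    sp = random_species(rng, labels)
    while True:
        genes = []
        for _ in range(rng.randint(1, k_max)):
            gl = labels if full_coverage else rng.sample(labels, rng.randint(2, n))
            genes.append(random_multree(rng, gl, max_mult=3))
        prof = Profile(genes)
        if len(prof.union_labels) >= 3:
            return sp, prof


class TestSprApply:
    def test_prune_leaf_regraft_hand_trace(self, quartet_ab_cd):
        t = quartet_ab_cd
        d_leaf = next(v for v, lab in t.leaf_labels.items() if lab == "d")
        b_leaf = next(v for v, lab in t.leaf_labels.items() if lab == "b")
        prune_edge = tuple(sorted((d_leaf, t.adj[d_leaf][0])))
        b_edge = tuple(sorted((b_leaf, t.adj[b_leaf][0])))
        out = spr_apply(t, SprMove(prune_edge, d_leaf, b_edge))
        assert out.same_topology(species("((b,d),(a,c));"))

    def test_regraft_at_original_attachment_is_identity(self, quartet_ab_cd):
        t = quartet_ab_cd
        for edge, pruned, rem in _prune_directions(t):
            keep = edge[0] if pruned == edge[1] else edge[1]
            # the edge formed by suppressing the old attachment vertex: putting
            # the subtree back there reproduces the input tree
            merged = tuple(sorted(w for w in t.adj[keep] if w != pruned))
            out = spr_apply(t, SprMove(edge, pruned, merged))
            assert out.same_topology(t)

    def test_label_multiset_conserved(self):
        rng = random.Random(1)
        for _ in range(20):
            t = random_species(rng, list("abcdef"))
            for edge, pruned, rem in _prune_directions(t):
                e = sorted({tuple(sorted((u, v))) for u in rem for v in rem[u]})[0]
                out = spr_apply(t, SprMove(edge, pruned, e))
                assert out.label_multiset == t.label_multiset
                assert out.is_binary

    def test_regraft_inside_pruned_subtree_raises(self, quartet_ab_cd):
        t = quartet_ab_cd
        (internal,) = t.internal_edges()
        u, v = internal
        bad = next(
            tuple(sorted((v, w))) for w in t.adj[v] if w != u
        )
        with pytest.raises(TreeError):
            spr_apply(t, SprMove(tuple(sorted(internal)), v, bad))


class TestNeighborhood:
    def test_quartet_has_two_neighbors(self, quartet_ab_cd):
        nbrs = spr_neighborhood(quartet_ab_cd)
        assert len(nbrs) == 2
        keys = {n.splits() for n in nbrs}
        assert keys == {
            species("((a,c),(b,d));").splits(),
            species("((a,d),(b,c));").splits(),
        }

    def test_five_taxa_has_twelve_neighbors(self):
        assert len(spr_neighborhood(species("(((a,b),c),(d,e));"))) == 12

    def test_neighbors_keep_label_set(self):
        t = species("(((a,b),c),(d,e));")
        assert all(n.label_set == t.label_set for n in spr_neighborhood(t))

    def test_too_small_tree(self):
        assert spr_neighborhood(species("(a,b,c);")) == []


class TestRegraftOrder:
    def test_path_euler_tour(self):
        adj = {0: [1], 1: [0, 2], 2: [1]}
        assert regraft_order(adj, 0) == [(0, 1), (1, 2), (2, 1), (1, 0)]

    def test_walk_properties(self):
        rng = random.Random(3)
        for _ in range(20):
            t = random_species(rng, list("abcdefgh"))
            for edge, pruned, rem in _prune_directions(t):
                start = min(v for v in rem if len(rem[v]) == 1)
                walk = regraft_order(rem, start)
                n_edges = sum(len(x) for x in rem.values()) // 2
                assert len(walk) == 2 * n_edges
                assert start in walk[0]
                counts = {}
                for e in walk:
                    counts[tuple(sorted(e))] = counts.get(tuple(sorted(e)), 0) + 1
                assert set(counts.values()) <= {2}
                for e1, e2 in zip(walk, walk[1:]):
                    assert set(e1) & set(e2)


class TestIncrementalScoring:
    def test_single_quartet_gene_scores(self, quartet_ab_cd):
        prof = Profile([parse_newick("((a,b),(c,d));")])
        for move, score in score_neighborhood(prof, quartet_ab_cd):
            realized = spr_apply(quartet_ab_cd, move)
            if realized.same_topology(quartet_ab_cd):
                assert score == 0
            else:
                assert score == 2

    def test_matches_from_scratch_oracle(self):
        rng = random.Random(7)
        for _ in range(25):
            sp, prof = random_instance(rng)
            for move, score in score_neighborhood(prof, sp):
                assert score == rf_profile(prof, spr_apply(sp, move))

    def test_update_sets_small_and_ledger_exact(self):
        """Full label coverage: at most 4 vertex-function changes per regraft
        and the distance moves by exactly 2|L| - 2|G|."""
        rng = random.Random(11)
        for _ in range(15):
            sp, prof = random_instance(rng, full_coverage=True)
            stats = SearchStats(collect_deltas=True)
            score_neighborhood(prof, sp, stats)
            for d in stats.deltas:
                assert len(d.changed) <= 4
                assert d.delta_surviving == 0
                assert d.rf_after - d.rf_before == 2 * len(d.lost) - 2 * len(d.gained)

    def test_generalized_ledger_with_missing_taxa(self):
        rng = random.Random(13)
        for _ in range(15):
            sp, prof = random_instance(rng)
            stats = SearchStats(collect_deltas=True)
            score_neighborhood(prof, sp, stats)
            for d in stats.deltas:
                assert len(d.changed) <= 4
                assert (
                    d.rf_after - d.rf_before
                    == 2 * len(d.lost) - 2 * len(d.gained) + d.delta_surviving
                )

    def test_disjoint_pruned_subtree_scores_constant(self):
        """A pruned subtree sharing no label with a gene leaves that gene's
        score unchanged across every regraft."""
        sp = species("(((a,b),c),((e,f),d));")
        gene = parse_newick("((a,b),(c,d));")
        prof = Profile([gene])
        base = rf_profile(prof, sp)
        stats = SearchStats()
        scored = score_neighborhood(prof, sp, stats)
        assert stats.skipped_gene_walks > 0
        ef = {"e", "f"}
        for move, score in scored:
            realized = spr_apply(sp, move)
            # moves pruning the {e,f} clade never change the gene's score
            pruned_labels = {
                sp.leaf_labels[v]
                for v in sp.component_vertices(
                    away_from=(
                        move.prune_edge[0]
                        if move.pruned_side == move.prune_edge[1]
                        else move.prune_edge[1]
                    ),
                    start=move.pruned_side,
                )
                if v in sp.leaf_labels
            }
            if pruned_labels == ef:
                assert score == base

    def test_mapping_updates_bounded(self):
        rng = random.Random(17)
        stats = SearchStats()
        for _ in range(10):
            sp, prof = random_instance(rng)
            score_neighborhood(prof, sp, stats)
        assert stats.mean_mapping_updates_per_regraft <= 8

    def test_work_scales_linearly_in_gene_count(self):
        rng = random.Random(19)
        labels = list("abcdefgh")
        sp = random_species(rng, labels)
        genes = [random_multree(rng, labels, 2) for _ in range(8)]
        s1, s2 = SearchStats(), SearchStats()
        score_neighborhood(Profile(genes[:4]), sp, s1)
        score_neighborhood(Profile(genes), sp, s2)
        ratio = s2.regraft_updates / s1.regraft_updates
        assert 1.5 <= ratio <= 2.5


class TestSearchStep:
    def test_recovers_quartet(self, quartet_ab_cd, quartet_ac_bd):
        prof = Profile([parse_newick("((a,b),(c,d));") for _ in range(3)])
        out = spr_search_step(prof, quartet_ac_bd)
        assert out.same_topology(quartet_ab_cd)
        assert rf_profile(prof, out) == 0

    def test_fixed_point(self, quartet_ab_cd):
        prof = Profile([parse_newick("((a,b),(c,d));")])
        out = spr_search_step(prof, quartet_ab_cd)
        assert out is quartet_ab_cd

    def test_never_worse(self):
        rng = random.Random(23)
        for _ in range(10):
            sp, prof = random_instance(rng)
            out = spr_search_step(prof, sp)
            assert rf_profile(prof, out) <= rf_profile(prof, sp)


class TestGreedyInit:
    def test_single_gene_always_perfect(self):
        prof = Profile([parse_newick("(a,b,(c,d));")])
        for seed in range(10):
            t = greedy_init(prof, seed)
            assert rf_profile(prof, t) == 0

    def test_deterministic(self):
        rng = random.Random(29)
        sp, prof = random_instance(rng, n_min=6, n_max=8)
        assert write_newick(greedy_init(prof, 5)) == write_newick(greedy_init(prof, 5))

    def test_covers_all_labels_and_binary(self):
        rng = random.Random(31)
        sp, prof = random_instance(rng, n_min=5, n_max=9)
        t = greedy_init(prof, 0)
        assert t.label_set == prof.union_labels
        assert t.is_binary
        assert max(t.label_multiset.values()) == 1

    def test_too_few_labels_raises(self):
        with pytest.raises(TreeError):
            greedy_init(Profile([parse_newick("(a,b);")]), 0)

    def test_attach_leaf(self):
        t = species("(a,b,c);")
        e = sorted(tuple(sorted(x)) for x in t.edges())[0]
        out = attach_leaf(t, e, "d")
        assert out.size == 4 and out.is_binary


class TestInfer:
    def test_identical_genes_recovered_with_zero_score(self):
        gene = parse_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        prof = Profile([gene.copy() for _ in range(4)])
        tree, trace = infer(prof, SearchConfig(seed=3, restarts=2))
        assert trace.final_score == 0
        assert SpeciesTree.from_multree(gene).same_topology(tree)

    def test_star_genes_stop_immediately(self):
        prof = Profile([parse_newick("(a,b,c,d);") for _ in range(3)])
        tree, trace = infer(prof, SearchConfig(seed=1))
        # all binary species trees tie, so no SPR iteration is accepted
        assert len(trace.scores) == 1
        assert trace.final_score == 3

    def test_scores_strictly_decrease(self):
        rng = random.Random(37)
        for seed in range(5):
            sp, prof = random_instance(rng, n_min=6, n_max=9, k_max=4)
            tree, trace = infer(prof, SearchConfig(seed=seed))
            assert all(b < a for a, b in zip(trace.scores, trace.scores[1:]))
            # final tree is a fixed point
            assert spr_search_step(prof, tree) is tree

    def test_empty_profile_raises(self):
        with pytest.raises(TreeError):
            infer(Profile([]), SearchConfig())

    def test_deterministic_given_seed(self):
        rng = random.Random(41)
        sp, prof = random_instance(rng, n_min=6, n_max=8)
        t1, _ = infer(prof, SearchConfig(seed=9, restarts=2))
        t2, _ = infer(prof, SearchConfig(seed=9, restarts=2))
        assert write_newick(t1) == write_newick(t2)
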