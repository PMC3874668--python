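"""Infer a species tree from discordant multi-copy gene trees.

The search minimizes the total RF distance from the gene trees: greedy leaf
addition builds a starting tree, then steepest-descent SPR moves run until
no neighbor improves the score.  The trace records the score after each
accepted move; the final score is the quantity being minimized (0 means the
tree displays every input gene tree).
"""

from mulrf import Profile, SearchConfig, infer, parse_newick, write_newick

genes = Profile(
    [
        parse_newick("(((a,b),(c,d)),((e,f),(g,h)));"),
        parse_newick("(((a,b),c),(d,((e,f),(g,h))));"),
        parse_newick("((((a,a),b),(c,d)),((e,f),(g,h)));"),  # duplicated a
        parse_newick("(((a,b),(c,d)),((e,g),(f,h)));"),      # one conflict
    ]
)

tree, trace = infer(genes, SearchConfig(seed=1, restarts=2))
print("inferred species tree:", write_newick(tree))
print("score per iteration:  ", trace.scores)
print("final total RF score: ", trace.final_score)

# The final score is the summed RF distance of the four gene trees to the
# inferred tree.  Genes 1 and 3 are displayed exactly (score 0, the
# duplicated copies of a notwithstanding); the residual 2 + 4 comes from the
# deliberately conflicting placements in genes 2 and 4, which no single
# species tree can reconcile with the others.
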