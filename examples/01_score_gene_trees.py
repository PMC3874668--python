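"""Score multi-copy gene trees against a candidate species tree.

The RF distance between a gene tree and a species tree counts the splits
that the two trees do not share, after the species tree is extended so that
a species sampled k times in the gene family appears as a k-leaf fan.
A distance of 0 means the species tree displays every grouping in the gene
tree; each conflicting split adds one (unmatched splits on either side each
count once).
"""

from mulrf import Profile, SpeciesTree, parse_newick, rf_multree, rf_profile

species = SpeciesTree.from_multree(parse_newick("(a,b,(c,d));"))
genes = Profile(
    [
        parse_newick("((a,a),(b,c));"),  # two copies of a, compatible
        parse_newick("((a,b),(a,c));"),  # copies of a split apart: conflict
        parse_newick("((a,b),(c,d));"),  # singly-labeled, identical topology
    ]
)

for i, gene in enumerate(genes, start=1):
    print(f"gene {i}: RF = {rf_multree(gene, species)}")
print(f"profile total: RF = {rf_profile(genes, species)}")

# gene 1 scores 0: the fan split {a,a}|{b,c} is realized by any species tree.
# gene 2 scores 2: the split {a,b}|{a,c} separates the two copies of a and
# can never match the extension, and one species-side split goes unmatched.
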