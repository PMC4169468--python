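"""Build the shared-ancestry matrix A from a strain phylogeny.

A's entry a_jk is the proportion of time since the root that strains j and
k spent as a single lineage; it is the between-strain covariance structure
the Brownian phylogenetic model assumes.
"""

from symbiocomp.phylo import read_newick, shared_ancestry_matrix

tree = read_newick("(((wA:1,wB:1):1,wC:2):1,wD:3);")
A = shared_ancestry_matrix(tree)
print(A.to_dataframe().round(3))
print()
print("wA and wB shared 2/3 of the tree's depth, wC joined them at 1/3,")
print("and wD diverged at the root (no shared ancestry, a = 0).")
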