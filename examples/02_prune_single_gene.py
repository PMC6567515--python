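"""Tree-based paralogy pruning of one gene, step by step.

A gene tree in which taxon A has two copies on opposite sides of the tree
(one is a contaminant or misassigned paralog) cannot keep both: the
pruner collapses weakly supported nodes, finds the maximally inclusive
subtree with at most one sequence per taxon, and resolves in-paralog
clades to the longest member.
"""

from phyloforge import (
    Alignment,
    GeneTree,
    OrthoGroup,
    PipelineConfig,
    Sequence,
    collapse_weak_nodes,
    prune_gene,
)

tree = GeneTree.from_newick(
    "(((A@1,B@1)0.99,(C@1,C@2)0.97)0.98,(D@1,A@2)0.99);"
)
aln = Alignment(
    "g1",
    [
        Sequence("A", "A@1", "ACDEFGHIKLMNPQRSTVWY"),
        Sequence("A", "A@2", "ACDEFGHIKLMNPQRSTVAA"),
        Sequence("B", "B@1", "ACDEFGHIKLMNPQRSTVWC"),
        Sequence("C", "C@1", "ACDEFGHIKLMNPQRSTV--"),
        Sequence("C", "C@2", "ACDEFGHIKLMNPQRSTVWD"),
        Sequence("D", "D@1", "ACDEFGHIKLMNPQRSTVWE"),
    ],
)

collapsed = collapse_weak_nodes(tree, 0.95)
print("collapsed tree:", collapsed.to_newick())

pruned = prune_gene(OrthoGroup("g1", alignment=aln, tree=tree), PipelineConfig())
print("selected subtree:", sorted(pruned.selected_leafset))
print("retained:", [s.seq_id for s in pruned.retained])
for r in pruned.removed:
    print(f"removed {r.seq_id}: {r.reason}")
# A@2 sits inside the (D, A@2) cherry, so taxon A is split across the
# tree: the maximal clean subtree excludes A@2 (outside-selected-subtree),
# and C's two clade-forming copies resolve to the longer C@2.
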