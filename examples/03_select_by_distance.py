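"""p-distance based sequence selection for one gene.

The permissive strategy needs no gene tree: it drops sequences whose
nearest other-taxon neighbour is too distant (putative contamination from
far outside the sampled clade), then keeps per taxon the sequence with
the smallest mean p-distance to the other taxa.
"""

from phyloforge import (
    Alignment,
    Sequence,
    exclude_divergent,
    p_distance,
    select_best_per_taxon,
)

aln = Alignment(
    "g1",
    [
        Sequence("A", "A@good", "ACDEFGHIKLMNPQRSTVWY"),
        Sequence("A", "A@divergent", "ACWWFGHIKLMNPQRSTWWY"),
        Sequence("B", "B@1", "ACDEFGHIKLMNPQRSTVWF"),
        Sequence("C", "C@1", "ACDEFGHIKLMNPQRSTVWW"),
        Sequence("X", "X@contam", "WWWWWWWWWWWWWWWWWWWW"),
    ],
)

for s in aln.members[:2]:
    print(f"d({s.seq_id}, B@1) = {p_distance(s, aln.get('B@1')):.2f}")

kept, removed = exclude_divergent(aln, divergence_threshold=0.25)
print("divergence-excluded:", [r.seq_id for r in removed])
final, removals = select_best_per_taxon(kept)
print("one per taxon:", [s.seq_id for s in final.members])
# X@contam has no neighbour within 0.25 and is excluded; A's two copies
# compete on mean distance to B and C, and the ordinary copy wins.
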