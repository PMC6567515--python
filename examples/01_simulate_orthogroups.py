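"""Simulate a small ground-truthed orthogroup dataset and write it to disk.

Each gene is an amino-acid alignment evolved on one random species tree,
with planted in-paralogs, out-paralogs, contaminants and fragments, plus
the true gene tree with simulated support values and a per-sequence truth
table.
"""

from collections import Counter

from phyloforge import SimParams, simulate_dataset
from phyloforge.simulate import write_dataset

params = SimParams(n_taxa=12, n_genes=20, root_sequence_length=200, rng_seed=42)
genes, truth, manifest = simulate_dataset(params)
write_dataset(genes, truth, manifest, "scratch/example_dataset")

labels = Counter(
    lab for g in truth.genes.values() for lab in g.labels.values()
)
print(f"simulated {len(genes)} genes for {params.n_taxa} taxa")
print(f"sequence truth labels: {dict(labels)}")
print(f"species tree: {truth.species_tree_newick[:70]}...")
# The label counts show how many sequences are clean orthologs versus
# planted problems; the pipeline's job is to recover one ortholog per
# taxon per gene without being fooled by the rest.
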