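import numpy as np
import pytest

from phyloforge.simulate import (
    SimParams,
    simulate_dataset,
    simulate_gene,
    simulate_species_tree,
    write_dataset,
)


def null_params(**overrides) -> SimParams:
    base = dict(
        n_taxa=10,
        n_genes=20,
        root_sequence_length=120,
        dropout_prob=0.0,
        inparalog_prob=0.0,
        outparalog_prob=0.0,
        contaminant_prob=0.0,
        fragment_prob=0.0,
        weak_support_prob=0.0,
        rng_seed=11,
    )
    base.update(overrides)
    return SimParams(**base)


class TestSpeciesTree:
    def test_two_taxa_cherry(self):
        t = simulate_species_tree(2, seed=1)
        assert t.n_leaves == 2 and t.n_internal_edges == 0

    def test_determinism(self):
        assert simulate_species_tree(12, seed=5).newick() == simulate_species_tree(12, seed=5).newick()
        assert simulate_species_tree(12, seed=5).newick() != simulate_species_tree(12, seed=6).newick()

    def test_tree_arithmetic(self):
        t = simulate_species_tree(20, seed=3)
        assert t.n_leaves == 20
        assert t.n_internal_edges == 18  # rooted binary: 2n-2 edges, n-2+... internal

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)


class TestSimulateGene:
    def test_null_model_one_per_taxon_species_topology(self):
        params = null_params()
        stree = simulate_species_tree(params.n_taxa, params.rng_seed)
        og, truth = simulate_gene(stree, params, 0)
        taxa = [s.taxon for s in og.alignment.members]
        assert sorted(taxa) == stree.leaf_names()  # exactly one per taxon
        assert set(truth.labels.values()) == {"ortholog"}
        # gene-tree topology equals species topology (same splits of taxa)
        gene_splits = {
            frozenset(lab.split("@")[0] for lab in og.tree.side_labels(u, v))
            for u, v in og.tree.internal_edges()
        }
        import dendropy

        st = dendropy.Tree.get(data=stree.newick(), schema="newick")
        species_splits = set()
        all_taxa = frozenset(stree.leaf_names())
        for node in st.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            species_splits.add(min(clade, all_taxa - clade, key=sorted))
        gene_canon = {min(s, all_taxa - s, key=sorted) for s in gene_splits}
        assert gene_canon == species_splits

    def test_contaminant_sits_with_donor_not_its_label(self):
        params = null_params(contaminant_prob=1.0, n_taxa=8)
        stree = simulate_species_tree(8, params.rng_seed)
        og, truth = simulate_gene(stree, params, 3)
        contam = next(s for s, l in truth.labels.items() if l == "contaminant")
        # the contaminant leaf is sister to a leaf of a *different* taxon (the
        # donor), i.e. its attachment node has a leaf neighbour not of its taxon
        node = og.tree.node_of_leaf(contam)
        attach = next(iter(og.tree.adjacency[node]))
        sisters = [
            og.tree.leaf_label[n]
            for n in og.tree.adjacency[attach]
            if n in og.tree.leaf_label and n != node
        ]
        assert sisters and all(s.split("@")[0] != contam.split("@")[0] for s in sisters)

    def test_fragment_length(self):
        params = null_params(fragment_prob=1.0, root_sequence_length=200,
                             fragment_fraction_range=(0.5, 0.5))
        stree = simulate_species_tree(params.n_taxa, params.rng_seed)
        og, truth = simulate_gene(stree, params, 0)
        frag = next(s for s, l in truth.labels.items() if l.startswith("fragment"))
        seq = og.alignment.get(frag)
        assert seq.ungapped_length == 100
        assert len(seq.residues) == 200  # terminal gaps pad the true alignment

    def test_inparalog_is_extra_copy_of_one_taxon(self):
        params = null_params(inparalog_prob=1.0)
        stree = simulate_species_tree(params.n_taxa, params.rng_seed)
        og, truth = simulate_gene(stree, params, 1)
        assert list(truth.labels.values()).count("inparalog") == 1
        taxa = [s.taxon for s in og.alignment.members]
        assert len(taxa) == params.n_taxa + 1
        assert len(set(taxa)) == params.n_taxa


class TestSimulateDataset:
    def test_manifest_echoes_params(self):
        params = null_params(n_genes=3)
        _, _, manifest = simulate_dataset(params)
        assert manifest["rng_seed"] == params.rng_seed
        assert manifest["n_taxa"] == params.n_taxa
        assert manifest["dropout_prob"] == params.dropout_prob

    def test_reruns_byte_identical(self, tmp_path):
        params = null_params(n_genes=5, dropout_prob=0.3, contaminant_prob=0.3,
                             outparalog_prob=0.3, weak_support_prob=0.2)
        for d in ("a", "b"):
            genes, truth, manifest = simulate_dataset(params)
            write_dataset(genes, truth, manifest, tmp_path / d)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_different_seeds_differ(self):
        g1, _, _ = simulate_dataset(null_params(n_genes=2, rng_seed=1))
        g2, _, _ = simulate_dataset(null_params(n_genes=2, rng_seed=2))
        assert g1[0].alignment.members != g2[0].alignment.members

    def test_contaminated_gene_fraction_tracks_probability(self):
        params = null_params(n_genes=400, n_taxa=6, root_sequence_length=60,
                             contaminant_prob=0.25, rng_seed=5)
        genes, truth, _ = simulate_dataset(params)
        frac = np.mean(
            [
                any(l == "contaminant" for l in truth.genes[g.gene_id].labels.values())
                for g in genes
            ]
        )
        # binomial: sd of the fraction at n=400 is ~0.022; allow 3 sd
        assert frac == pytest.approx(0.25, abs=0.065)
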