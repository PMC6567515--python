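import numpy as np
import pytest

from phyloforge.model import OrthoGroup, PipelineConfig
from phyloforge.pruner import (
    UnprunableGeneError,
    candidate_subtrees,
    collapse_weak_nodes,
    is_valid,
    prune_gene,
    resolve_inparalogs,
    select_maximal_subtree,
)
from phyloforge.tree import GeneTree
from conftest import build_random_tree, mkaln
from oracle_pruner import best_subtree_bruteforce


def _tree(nwk: str) -> GeneTree:
    return GeneTree.from_newick(nwk)


class TestCollapse:
    def test_weak_edge_becomes_polytomy(self):
        t = collapse_weak_nodes(_tree("((a,b)0.90,(c,d)0.99);"), 0.95)
        # the (a,b) clade dissolves; the cd|ab split survives (canonical key
        # is the lexicographically smaller side)
        assert t._split_supports() == {frozenset({"a", "b"}): 0.99}

    def test_all_strong_is_noop(self):
        t0 = _tree("((a,b)1.0,(c,d)1.0);")
        assert collapse_weak_nodes(t0, 0.95) == t0

    def test_all_weak_gives_star(self):
        t = collapse_weak_nodes(_tree("((a,b)0.5,(c,d)0.5);"), 0.95)
        assert list(t.internal_edges()) == []

    def test_absent_support_collapsed(self):
        t = collapse_weak_nodes(_tree("((a,b),(c,d)0.99);"), 0.95)
        assert t._split_supports() == {frozenset({"a", "b"}): 0.99}

    def test_exact_threshold_kept(self):
        # the rule is strictly-below
        t = collapse_weak_nodes(_tree("((a,b)0.95,(c,d)0.99);"), 0.95)
        assert len(list(t.internal_edges())) == 2


class TestCandidates:
    def test_quartet(self):
        cands = set(candidate_subtrees(_tree("((a,b),(c,d));")))
        expected = {
            frozenset("abcd"),
            frozenset("ab"),
            frozenset("cd"),
            frozenset("bcd"),
            frozenset("acd"),
            frozenset("abd"),
            frozenset("abc"),
        }
        assert cands == expected

    def test_star(self):
        t = collapse_weak_nodes(_tree("((a,b)0.5,(c,d)0.5);"), 0.95)
        cands = set(candidate_subtrees(t))
        assert cands == {
            frozenset("abcd"),
            frozenset("bcd"),
            frozenset("acd"),
            frozenset("abd"),
            frozenset("abc"),
        }

    def test_two_leaves(self):
        assert candidate_subtrees(_tree("(a,b);")) == [frozenset("ab")]


class TestValidity:
    def test_clade_case(self):
        t = _tree("((A@1,A@2)1.0,(B@1,C@1)1.0);")
        taxon_of = {l: l.split("@")[0] for l in t.leaves()}
        assert is_valid(frozenset(t.leaves()), t, taxon_of)

    def test_split_taxon_invalid(self):
        t = _tree("((A@1,B@1)1.0,(C@1,A@2)1.0);")
        taxon_of = {l: l.split("@")[0] for l in t.leaves()}
        assert not is_valid(frozenset(t.leaves()), t, taxon_of)

    def test_same_polytomy_valid(self):
        star = collapse_weak_nodes(_tree("((A@1,A@2)0.5,(B@1,C@1)0.5);"), 0.95)
        taxon_of = {l: l.split("@")[0] for l in star.leaves()}
        assert is_valid(frozenset(star.leaves()), star, taxon_of)

    def test_non_candidate_errors(self):
        t = _tree("((a,b),(c,d));")
        with pytest.raises(ValueError):
            is_valid(frozenset("ac"), t, {l: l for l in "abcd"})


class TestSelection:
    def test_split_taxon_three_leaf_complement(self):
        t = _tree("((A@1,B@1)1.0,(C@1,A@2)1.0);")
        taxon_of = {l: l.split("@")[0] for l in t.leaves()}
        # both 3-leaf complements have 3 taxa; name tie-break picks A@1's side
        assert select_maximal_subtree(t, taxon_of) == frozenset({"A@1", "B@1", "C@1"})

    def test_inparalog_clade_keeps_full_set(self):
        t = _tree("((A@1,A@2)1.0,(B@1,C@1)1.0);")
        taxon_of = {l: l.split("@")[0] for l in t.leaves()}
        assert select_maximal_subtree(t, taxon_of) == frozenset(t.leaves())

    def test_collapse_rescues_inparalogs(self):
        # strongly supported: A's copies split -> a copy is cut; weakly
        # supported: collapse merges them into one polytomy -> full set valid
        strong = _tree("((A@1,B@1)1.0,(A@2,C@1)1.0);")
        weak = _tree("((A@1,B@1)0.5,(A@2,C@1)0.5);")
        taxon_of = {l: l.split("@")[0] for l in strong.leaves()}
        assert len(select_maximal_subtree(collapse_weak_nodes(strong, 0.95), taxon_of)) == 3
        collapsed = collapse_weak_nodes(weak, 0.95)
        assert select_maximal_subtree(collapsed, taxon_of) == frozenset(strong.leaves())

    def test_single_taxon_gene_unprunable(self):
        t = _tree("((A@1,A@2)1.0,(A@3,A@4)1.0);")
        with pytest.raises(UnprunableGeneError):
            select_maximal_subtree(t, {l: "A" for l in t.leaves()})

    def test_matches_bruteforce_oracle(self, rng):
        """Implementation agrees with exhaustive subset enumeration."""
        for _ in range(150):
            n = int(rng.integers(4, 11))
            tree, taxon_of, lengths = build_random_tree(rng, n)
            collapsed = collapse_weak_nodes(tree, 0.95)
            expected = best_subtree_bruteforce(collapsed, taxon_of, lengths)
            if expected is None:
                with pytest.raises(UnprunableGeneError):
                    select_maximal_subtree(collapsed, taxon_of, lengths)
            else:
                assert select_maximal_subtree(collapsed, taxon_of, lengths) == expected

    def test_total_collapse_brackets_behavior(self, rng):
        """At threshold > 1 every tree is a star, where any multi-copy taxon
        shares the central polytomy: nothing is lost except via in-paralog
        resolution, so the star always retains the most taxa."""
        for _ in range(40):
            tree, taxon_of, lengths = build_random_tree(rng, int(rng.integers(4, 10)))
            if len(set(taxon_of.values())) < 2:
                continue
            star = collapse_weak_nodes(tree, 1.01)
            assert list(star.internal_edges()) == []
            sel = select_maximal_subtree(star, taxon_of, lengths)
            assert sel == frozenset(tree.leaves())  # full set valid on a star
            for thr in (0.95, 0.5):
                try:
                    sub = select_maximal_subtree(
                        collapse_weak_nodes(tree, thr), taxon_of, lengths
                    )
                    k = len({taxon_of[l] for l in sub})
                except UnprunableGeneError:
                    k = 0
                assert k <= len({taxon_of[l] for l in sel})


class TestResolveInparalogs:
    def test_longest_kept(self):
        aln = mkaln("g", {"A@1": "A" * 200, "A@2": "A" * 150 + "-" * 50, "B@1": "C" * 200})
        pg = resolve_inparalogs(frozenset(["A@1", "A@2", "B@1"]), aln)
        assert {s.seq_id for s in pg.retained} == {"A@1", "B@1"}
        reasons = {r.seq_id: r.reason for r in pg.removed}
        assert reasons == {"A@2": "shorter-inparalog"}

    def test_equal_length_tie_smaller_id(self):
        aln = mkaln("g", {"A@s2": "A" * 100, "A@s1": "A" * 100, "B@1": "C" * 100})
        pg = resolve_inparalogs(frozenset(["A@s1", "A@s2", "B@1"]), aln)
        assert {s.seq_id for s in pg.retained} == {"A@s1", "B@1"}

    def test_accounting_partition(self):
        aln = mkaln("g", {"A@1": "A" * 10, "A@2": "C" * 10, "B@1": "A" * 10})
        pg = resolve_inparalogs(frozenset(["A@1", "A@2", "B@1"]), aln)
        all_ids = {s.seq_id for s in aln.members}
        assert {s.seq_id for s in pg.retained} | {r.seq_id for r in pg.removed} == all_ids


class TestPruneGene:
    def test_missing_tree_errors(self):
        og = OrthoGroup(gene_id="g", alignment=mkaln("g", {"A@1": "AAAA", "B@1": "CCCC", "C@1": "AAAA"}))
        with pytest.raises(Exception, match="tree"):
            prune_gene(og, PipelineConfig())

    def test_never_two_sequences_per_taxon(self, rng):
        for _ in range(30):
            tree, taxon_of, _ = build_random_tree(rng, int(rng.integers(4, 10)))
            cols = 30
            aln = mkaln(
                "g",
                {lab: "".join(rng.choice(list("ACDE"), cols)) for lab in sorted(tree.leaves())},
                sep="@",
            )
            og = OrthoGroup(gene_id="g", alignment=aln, tree=tree)
            try:
                pg = prune_gene(og, PipelineConfig())
            except UnprunableGeneError:
                continue
            taxa = [s.taxon for s in pg.retained]
            assert len(taxa) == len(set(taxa))
            assert {s.seq_id for s in pg.retained} | {r.seq_id for r in pg.removed} == set(
                tree.leaves()
            )
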