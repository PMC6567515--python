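"""Strict tree-based paralogy screening (the conservative strategy).

Each gene tree is screened for evidence of paralogy or contamination:
weakly supported nodes are first collapsed into polytomies, then the
maximally inclusive subtree is selected in which every taxon is
represented by at most one sequence — or, where a taxon has several
sequences, they form a clade or sit in the same polytomy (in-paralogs).
Sequences outside the selected subtree (putative out-paralogs and
contaminants) are deleted; within it, each multi-copy taxon is resolved
to its longest sequence.

"Maximally inclusive" is scored taxon-count first (matrix occupancy is
the quantity at stake), then leaf count, then total ungapped length, then
a lexicographic tie-break on the sorted leaf names, making the whole
procedure deterministic.  Candidate subtrees of an unrooted tree are
exactly the full leaf set plus the two leaf sets obtained by cutting each
edge.  Absent supports are treated as below threshold and collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from phyloforge.model import Alignment, OrthoGroup, PhyloforgeError, Removal, Sequence
from phyloforge.tree import GeneTree


class UnprunableGeneError(PhyloforgeError):
    """No candidate subtree with at least two taxa satisfies the one-per-taxon rule."""


@dataclass
class PrunedGene:
    """Outcome of pruning one gene: retained sequences plus a full audit."""

    gene_id: str
    retained: list[Sequence]
    removed: list[Removal]
    selected_leafset: frozenset[str]

    def __post_init__(self) -> None:
        taxa = [s.taxon for s in self.retained]
        if len(taxa) != len(set(taxa)):
            raise ValueError("PrunedGene retains more than one sequence for a taxon")


def collapse_weak_nodes(tree: GeneTree, threshold: float = 0.95) -> GeneTree:
    """Contract internal edges with support below ``threshold`` or absent."""
    return tree.collapse(threshold)


def candidate_subtrees(tree: GeneTree) -> list[frozenset[str]]:
    """All leaf sets realizable as subtrees of the unrooted tree.

    The full leaf set, plus both sides of every edge cut; singletons are
    excluded and duplicates removed.  Deterministic order (by size
    descending, then sorted labels).
    """
    full = frozenset(tree.leaves())
    cands = {full}
    for u, v in tree.edges():
        side = tree.side_labels(u, v)
        for s in (side, full - side):
            if len(s) >= 2:
                cands.add(s)
    return sorted(cands, key=lambda s: (-len(s), tuple(sorted(s))))


def is_valid(
    leafset: frozenset[str], tree: GeneTree, taxon_of: Mapping[str, str]
) -> bool:
    """Does the candidate satisfy the one-sequence-per-taxon rule?

    For every taxon with two or more leaves inside the candidate, either
    (i) some edge cut of the candidate subtree separates exactly that
    taxon's leaves from the rest of the candidate (a clade in the unrooted
    sense), or (ii) all of that taxon's leaves hang off one common node
    (the same polytomy).
    """
    leafset = frozenset(leafset)
    if leafset not in set(candidate_subtrees(tree)):
        raise ValueError("leafset is not a candidate subtree of this tree")
    by_taxon: dict[str, set[str]] = {}
    for label in leafset:
        by_taxon.setdefault(taxon_of[label], set()).add(label)
    multi = [labels for labels in by_taxon.values() if len(labels) >= 2]
    if not multi:
        return True
    # Precompute, for every edge, its split restricted to the candidate.
    splits = []
    for u, v in tree.edges():
        side = tree.side_labels(u, v) & leafset
        if 0 < len(side) < len(leafset):
            splits.append(side)
    for labels in multi:
        if labels == leafset:  # whole candidate is one taxon: trivially a clade
            continue
        if any(side == labels or leafset - side == labels for side in splits):
            continue
        attachments = {next(iter(tree.adjacency[tree.node_of_leaf(l)])) for l in labels}
        if len(attachments) == 1:
            continue
        return False
    return True


def _valid_fast(
    cand: frozenset[str],
    splits: list[frozenset[str]],
    taxon_of: Mapping[str, str],
    attachment: Mapping[str, int],
) -> bool:
    """Validity check against precomputed edge splits (same rule as is_valid)."""
    by_taxon: dict[str, set[str]] = {}
    for label in cand:
        by_taxon.setdefault(taxon_of[label], set()).add(label)
    for labels in by_taxon.values():
        if len(labels) < 2 or labels == cand:
            continue
        if any(
            part == labels or cand - part == labels
            for part in (side & cand for side in splits)
            if 0 < len(part) < len(cand)
        ):
            continue
        if len({attachment[l] for l in labels}) == 1:
            continue
        return False
    return True


def select_maximal_subtree(
    tree: GeneTree,
    taxon_of: Mapping[str, str],
    lengths: Optional[Mapping[str, int]] = None,
) -> frozenset[str]:
    """The maximally inclusive valid candidate subtree.

    Valid candidates are ranked by (1) number of distinct taxa, (2) number
    of leaves, (3) total ungapped length of member sequences, then (4) the
    lexicographically smallest sorted leaf-name tuple.  Raises
    UnprunableGeneError when no valid candidate spans two or more taxa.
    """
    lengths = lengths or {}
    splits = [tree.side_labels(u, v) for u, v in tree.edges()]
    attachment = {
        lab: next(iter(tree.adjacency[n])) for n, lab in tree.leaf_label.items()
    }
    best: Optional[frozenset[str]] = None
    best_key = None
    for cand in candidate_subtrees(tree):
        if len({taxon_of[l] for l in cand}) < 2:
            continue
        if not _valid_fast(cand, splits, taxon_of, attachment):
            continue
        key = (
            len({taxon_of[l] for l in cand}),
            len(cand),
            sum(lengths.get(l, 0) for l in cand),
        )
        names = tuple(sorted(cand))
        if best is None or key > best_key[0] or (key == best_key[0] and names < best_key[1]):
            best, best_key = cand, (key, names)
    if best is None:
        raise UnprunableGeneError(
            "no valid candidate subtree spans two or more taxa"
        )
    return best


def resolve_inparalogs(
    leafset: frozenset[str], alignment: Alignment, stage: str = "prune"
) -> PrunedGene:
    """Keep one sequence per taxon inside the selected subtree.

    Multi-copy taxa (in-paralogs that formed a clade or shared a polytomy)
    are resolved to the sequence with the greatest ungapped length, ties
    to the lexicographically smaller seq_id.  Sequences outside the
    subtree are logged as removed.
    """
    removed: list[Removal] = []
    inside: dict[str, list[Sequence]] = {}
    for s in alignment.members:
        if s.seq_id in leafset:
            inside.setdefault(s.taxon, []).append(s)
        else:
            removed.append(Removal(stage, s.seq_id, "outside-selected-subtree"))
    retained: list[Sequence] = []
    for taxon in sorted(inside):
        copies = inside[taxon]
        winner = max(copies, key=lambda s: (s.ungapped_length, _neg(s.seq_id)))
        retained.append(winner)
        for s in copies:
            if s is not winner:
                removed.append(Removal(stage, s.seq_id, "shorter-inparalog"))
    return PrunedGene(
        gene_id=alignment.gene_id,
        retained=retained,
        removed=removed,
        selected_leafset=frozenset(leafset),
    )


def _neg(seq_id: str) -> tuple[int, ...]:
    # max() with this key prefers the lexicographically *smaller* seq_id.
    return tuple(-ord(c) for c in seq_id)


def prune_gene(orthogroup: OrthoGroup, config=None) -> PrunedGene:
    """Collapse weak nodes, select the maximal clean subtree, resolve in-paralogs.

    Requires the orthogroup to carry both an alignment and a gene tree
    whose leaves cover the alignment.  Deterministic for fixed inputs.
    """
    from phyloforge.model import PipelineConfig

    config = config or PipelineConfig()
    if orthogroup.alignment is None:
        raise PhyloforgeError(f"gene {orthogroup.gene_id}: no alignment to prune")
    if orthogroup.tree is None:
        raise PhyloforgeError(
            f"gene {orthogroup.gene_id}: pruning requires a gene tree "
            "(supply one per gene, or simulate inputs with trees)"
        )
    aln = orthogroup.alignment
    ids = {s.seq_id for s in aln.members}
    missing = ids - orthogroup.tree.leaves()
    if missing:
        raise PhyloforgeError(
            f"gene {orthogroup.gene_id}: alignment sequences absent from tree: "
            f"{sorted(missing)[:3]}..."
        )
    if len(aln.members) <= 2:
        return resolve_inparalogs(frozenset(ids), aln)
    tree = orthogroup.tree
    if tree.leaves() != ids:
        tree = tree.restrict(ids)
    collapsed = collapse_weak_nodes(tree, config.support_collapse_threshold)
    taxon_of = {s.seq_id: s.taxon for s in aln.members}
    lengths = {s.seq_id: s.ungapped_length for s in aln.members}
    leafset = select_maximal_subtree(collapsed, taxon_of, lengths)
    return resolve_inparalogs(leafset, aln)
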