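"""Alignment-level quality gates.

Three gates applied to each trimmed orthogroup alignment, in protocol
order: a minimum-length gate (alignments shorter than 50 columns are
discarded), an iterative pairwise-overlap filter (every retained pair of
sequences must share at least 20 residue-bearing columns, a prerequisite
for meaningful single-gene trees), and a minimum-taxon gate (genes sampled
for fewer than 10 distinct taxa are discarded).
"""

from __future__ import annotations

from phyloforge.model import Alignment, OrthoGroup, Removal, Sequence


def length_gate(alignment: Alignment, min_columns: int = 50) -> bool:
    """True if the alignment is long enough to keep (strictly-shorter rule)."""
    return alignment.n_columns >= min_columns


def pairwise_overlap(seq_a: Sequence, seq_b: Sequence) -> int:
    """Number of alignment columns where both sequences have a residue.

    'X' counts as a residue (it occupies a position); '-' does not.
    """
    a, b = seq_a.residues, seq_b.residues
    if len(a) != len(b):
        raise ValueError(
            f"aligned length mismatch: {seq_a.seq_id} ({len(a)}) vs "
            f"{seq_b.seq_id} ({len(b)})"
        )
    return sum(1 for x, y in zip(a, b) if x != "-" and y != "-")


def overlap_filter(
    alignment: Alignment, min_overlap: int = 20, stage: str = "overlap"
) -> tuple[Alignment, list[Removal]]:
    """Iteratively delete sequences that under-overlap some other sequence.

    While any retained pair overlaps by fewer than ``min_overlap`` columns,
    the shortest (ungapped) sequence among those failing the
    overlap-with-all-others criterion is deleted, ties broken by deleting
    the lexicographically larger seq_id, and the failing set is recomputed
    after every single removal.  Terminates with all remaining pairs at or
    above the threshold, or at most one sequence.
    """
    members = list(alignment.members)
    removals: list[Removal] = []
    while len(members) > 1:
        failing: list[Sequence] = []
        for s in members:
            worst = min(pairwise_overlap(s, t) for t in members if t is not s)
            if worst < min_overlap:
                failing.append(s)
        if not failing:
            break
        victim = min(failing, key=lambda s: (s.ungapped_length, _rev(s.seq_id)))
        members.remove(victim)
        removals.append(
            Removal(stage, victim.seq_id, f"pairwise-overlap<{min_overlap}")
        )
    return Alignment(alignment.gene_id, members), removals


def _rev(seq_id: str) -> tuple[int, ...]:
    # Inverts lexicographic order so min() deletes the *larger* seq_id on ties.
    return tuple(-ord(c) for c in seq_id)


def min_taxa_gate(orthogroup_or_alignment, min_taxa: int = 10) -> bool:
    """True if the gene samples at least ``min_taxa`` distinct taxa.

    Counts taxa, not sequences.  Accepts an OrthoGroup (preferring its
    alignment) or a bare Alignment.
    """
    obj = orthogroup_or_alignment
    if isinstance(obj, OrthoGroup):
        seqs = obj.alignment.members if obj.alignment is not None else obj.unaligned
    else:
        seqs = obj.members
    return len({s.taxon for s in seqs}) >= min_taxa
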