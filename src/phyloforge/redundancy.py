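"""Redundant-haplotype removal on unaligned orthogroups.

Before alignment, transcript sets typically contain exact duplicates and
fragments that are identical to a longer transcript wherever they overlap.
Both are redundant for phylogenetics and are removed here, keeping one
longest representative per set.  Redundancy is a within-taxon notion —
the goal is unique sequences for each taxon, and two taxa may genuinely
share a sequence in a conserved gene — so only sequences of the same
taxon are compared.  "Identical where they overlap" is operationalized
as exact substring containment of ungapped residues: transcript fragments
are contiguous, so a partial sequence identical to part of a longer one is
a substring of it.  Partial overlaps with mismatches are kept.
'X' is matched strictly, like any other letter.
"""

from __future__ import annotations

from phyloforge.model import Removal, Sequence


def remove_redundant(
    sequences: list[Sequence], stage: str = "redundancy"
) -> tuple[list[Sequence], list[Removal]]:
    """Drop sequences equal to, or contained in, a retained same-taxon sequence.

    Sequences are processed in decreasing ungapped length (ties by seq_id),
    so the longest representative always survives and, among exact
    duplicates, the lexicographically smaller seq_id is retained.  Returns
    the retained sequences in input order plus a removal log naming the
    retained partner for every removal.
    """
    order = sorted(sequences, key=lambda s: (-s.ungapped_length, s.seq_id))
    retained: list[Sequence] = []
    removals: list[Removal] = []
    for cand in order:
        partner = next(
            (
                kept
                for kept in retained
                if kept.taxon == cand.taxon and cand.ungapped() in kept.ungapped()
            ),
            None,
        )
        if partner is not None:
            removals.append(
                Removal(stage, cand.seq_id, f"redundant-with:{partner.seq_id}")
            )
        else:
            retained.append(cand)
    kept_ids = {s.seq_id for s in retained}
    return [s for s in sequences if s.seq_id in kept_ids], removals
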