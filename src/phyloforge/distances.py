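"""p-distance based sequence selection (the permissive strategy).

Instead of tree-based pruning, divergent sequences (putative contaminants
from outside the clade of interest) are excluded on raw p-distance, and
each taxon's best sequence is the one with the smallest average p-distance
to the sequences of all other taxa.  The p-distance between two aligned
sequences is the fraction of mismatching residues over the columns where
both have a residue; columns where either sequence has an ambiguous 'X'
are excluded from both counts.  No chimeric merging of same-taxon
fragments is performed: one whole sequence is always chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from phyloforge.model import Alignment, Removal, Sequence

logger = logging.getLogger(__name__)


def p_distance(seq_a: Sequence, seq_b: Sequence) -> float:
    """Proportion of differing residues over comparable columns.

    Comparable columns have a non-gap, non-'X' residue in both sequences.
    With zero comparable columns the distance is maximal (1.0), with a
    logged warning: two sequences that never overlap carry no evidence of
    similarity.
    """
    a, b = seq_a.residues, seq_b.residues
    if len(a) != len(b):
        raise ValueError(
            f"aligned length mismatch: {seq_a.seq_id} ({len(a)}) vs "
            f"{seq_b.seq_id} ({len(b)})"
        )
    comparable = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in "-X" or y in "-X":
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        logger.warning(
            "no comparable columns between %s and %s; distance set to 1.0",
            seq_a.seq_id,
            seq_b.seq_id,
        )
        return 1.0
    return mismatches / comparable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distances for one gene."""

    gene_id: str
    labels: list[str]
    d: np.ndarray
    comparable_columns: np.ndarray

    def value(self, id_a: str, id_b: str) -> float:
        i, j = self.labels.index(id_a), self.labels.index(id_b)
        return float(self.d[i, j])


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All pairwise p-distances of an alignment (vectorized over columns)."""
    labels = [s.seq_id for s in alignment.members]
    n = len(labels)
    if n == 0:
        raise ValueError("cannot compute distances for an empty alignment")
    arr = np.frombuffer(
        "".join(s.residues for s in alignment.members).encode("ascii"), dtype="S1"
    ).reshape(n, -1)
    usable = (arr != b"-") & (arr != b"X")
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = usable[i] & usable[i + 1 :]
        c = both.sum(axis=1)
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            dij = np.where(c > 0, mism / np.maximum(c, 1), 1.0)
        d[i, i + 1 :] = dij
        d[i + 1 :, i] = dij
        comp[i, i + 1 :] = c
        comp[i + 1 :, i] = c
    return DistanceMatrix(alignment.gene_id, labels, d, comp)


def exclude_divergent(
    alignment: Alignment,
    divergence_threshold: float = 0.25,
    stage: str = "divergence",
) -> tuple[Alignment, list[Removal]]:
    """Remove sequences far from every other taxon's sequences.

    A sequence is excluded when its minimum p-distance to any sequence of
    a *different* taxon exceeds the threshold — a genuine ortholog has a
    near neighbour in some related taxon, whereas a contaminant or highly
    divergent copy does not.  Single-taxon genes are returned unchanged.
    """
    if len(alignment.taxa) < 2:
        return alignment, []
    dm = distance_matrix(alignment)
    taxa = [s.taxon for s in alignment.members]
    removals: list[Removal] = []
    keep: list[Sequence] = []
    for i, s in enumerate(alignment.members):
        other = [j for j in range(len(taxa)) if taxa[j] != s.taxon]
        nearest = min(dm.d[i, j] for j in other)
        if nearest > divergence_threshold:
            removals.append(
                Removal(stage, s.seq_id, f"min-other-taxon-distance>{divergence_threshold}")
            )
        else:
            keep.append(s)
    return Alignment(alignment.gene_id, keep), removals


def select_best_per_taxon(
    alignment: Alignment, stage: str = "select"
) -> tuple[Alignment, list[Removal]]:
    """Keep, per taxon, the sequence closest on average to the other taxa.

    For each taxon with several sequences the candidate minimizing the
    mean p-distance to all sequences of other taxa is retained; ties go to
    the greater ungapped length, then the smaller seq_id.  A taxon's own
    duplicates do not enter the average, so they cannot vote for each
    other.  Single-copy taxa pass through unchanged.
    """
    dm = distance_matrix(alignment)
    taxa = [s.taxon for s in alignment.members]
    by_taxon: dict[str, list[int]] = {}
    for i, t in enumerate(taxa):
        by_taxon.setdefault(t, []).append(i)
    removals: list[Removal] = []
    keep_ids: set[str] = set()
    for taxon, idxs in by_taxon.items():
        if len(idxs) == 1:
            keep_ids.add(alignment.members[idxs[0]].seq_id)
            continue
        other = [j for j, t in enumerate(taxa) if t != taxon]

        def rank(i: int):
            s = alignment.members[i]
            mean_d = float(np.mean(dm.d[i, other])) if other else 0.0
            return (mean_d, -s.ungapped_length, s.seq_id)

        winner = min(idxs, key=rank)
        keep_ids.add(alignment.members[winner].seq_id)
        for i in idxs:
            if i != winner:
                removals.append(
                    Removal(stage, alignment.members[i].seq_id, "worse-mean-p-distance")
                )
    kept = [s for s in alignment.members if s.seq_id in keep_ids]
    return Alignment(alignment.gene_id, kept), removals
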