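"""Core domain types shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from phyloforge.tree import GeneTree

#: The amino-acid alphabet admitted into the pipeline: the 20 standard
#: residues, 'X' for an ambiguous residue, and '-' for a gap.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X-")
GAP = "-"


class PhyloforgeError(Exception):
    """Base class for all package errors."""


class MalformedHeaderError(PhyloforgeError):
    pass


class FastaParseError(PhyloforgeError):
    pass


class NewickParseError(PhyloforgeError):
    pass


@dataclass(frozen=True)
class Sequence:
    """A labelled amino-acid sequence.

    ``taxon`` is the species/OTU label; ``seq_id`` is the full record
    identifier, unique within a gene; ``residues`` is an upper-case string
    over the 20 amino-acid letters plus 'X' (ambiguous) and '-' (gap).
    """

    taxon: str
    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon label must be non-empty")
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)!r} in sequence {self.seq_id!r}"
            )

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    def ungapped(self) -> str:
        """Residues with all gap characters stripped."""
        return self.residues.replace(GAP, "")

    def with_residues(self, residues: str) -> "Sequence":
        return dataclasses.replace(self, residues=residues)


@dataclass
class Alignment:
    """An aligned orthogroup: equal-length sequences of one gene."""

    gene_id: str
    members: list[Sequence]

    def __post_init__(self) -> None:
        ids = [s.seq_id for s in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate seq_id in alignment {self.gene_id!r}")
        lengths = {len(s.residues) for s in self.members}
        if len(lengths) > 1:
            raise ValueError(
                f"alignment {self.gene_id!r} has ragged rows: lengths {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.members[0].residues) if self.members else 0

    @property
    def taxa(self) -> set[str]:
        return {s.taxon for s in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def get(self, seq_id: str) -> Sequence:
        for s in self.members:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)

    def subset(self, seq_ids) -> "Alignment":
        keep = set(seq_ids)
        return Alignment(self.gene_id, [s for s in self.members if s.seq_id in keep])


@dataclass(frozen=True)
class Removal:
    """One sequence removed by one stage, with the rule that removed it."""

    stage: str
    seq_id: str
    reason: str


@dataclass
class OrthoGroup:
    """One gene flowing through the pipeline.

    Carries the unaligned and/or aligned sequences, optionally the gene
    tree, and an append-only log of every removal so that each stage's
    arithmetic (input = retained + removed) is replayable.
    """

    gene_id: str
    unaligned: Optional[list[Sequence]] = None
    alignment: Optional[Alignment] = None
    tree: Optional["GeneTree"] = None
    stage_log: list[Removal] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unaligned is None and self.alignment is None:
            raise ValueError(
                f"orthogroup {self.gene_id!r} needs unaligned or aligned sequences"
            )

    def log_removal(self, stage: str, seq_id: str, reason: str) -> None:
        self.stage_log.append(Removal(stage, seq_id, reason))

    def removed_ids(self) -> set[str]:
        return {r.seq_id for r in self.stage_log}


@dataclass
class PipelineConfig:
    """Thresholds and conventions for one pipeline run.

    Defaults follow the published protocol: collapse gene-tree nodes
    supported below 0.95, require 20 residues of pairwise overlap, drop
    alignments shorter than 50 columns and genes sampled for fewer than
    10 taxa.  ``divergence_threshold`` is the maximum p-distance a
    sequence may have to its nearest other-taxon neighbour before it is
    excluded as divergent (the permissive strategy's contamination gate).
    """

    support_collapse_threshold: float = 0.95
    min_pairwise_overlap: int = 20
    min_alignment_columns: int = 50
    min_taxa_per_gene: int = 10
    divergence_threshold: float = 0.25
    header_separator: str = "@"
    missing_fill_symbol: str = "-"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.support_collapse_threshold <= 1.0:
            raise ValueError("support_collapse_threshold must be in [0, 1]")
        if not 0.0 <= self.divergence_threshold <= 1.0:
            raise ValueError("divergence_threshold must be in [0, 1]")
        for name in ("min_pairwise_overlap", "min_alignment_columns", "min_taxa_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if len(self.header_separator) != 1:
            raise ValueError("header_separator must be a single character")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
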