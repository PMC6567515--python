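"""FASTA and Newick I/O with the taxon-in-header convention.

The taxon label is encoded in each FASTA header before a configurable
separator (default ``@``), e.g. ``Tobrilus_sp@TR1_c0_g1``; the sequence id
is the full header, which makes ids globally unique and lets gene trees
reference them directly.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence as SequenceT

from Bio import SeqIO

from phyloforge.model import (
    FastaParseError,
    MalformedHeaderError,
    PhyloforgeError,
    Sequence,
)
from phyloforge.tree import GeneTree


def parse_header(header: str, separator: str = "@") -> tuple[str, str]:
    """Split a FASTA header into (taxon, seq_id).

    The taxon is the text before the *first* separator; the seq_id is the
    full header.  A header without the separator is malformed.
    """
    if not header:
        raise MalformedHeaderError("empty FASTA header")
    if separator not in header:
        raise MalformedHeaderError(
            f"header {header!r} lacks the taxon separator {separator!r}"
        )
    taxon = header.split(separator, 1)[0]
    if not taxon:
        raise MalformedHeaderError(f"header {header!r} has an empty taxon field")
    return taxon, header


def read_fasta(path, separator: str = "@") -> list[Sequence]:
    """Read an amino-acid FASTA file into Sequence records.

    Residues are upper-cased; file order is preserved; duplicate headers,
    empty files and illegal characters are rejected with named errors.
    """
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records")
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        header = rec.description
        if header in seen:
            raise FastaParseError(f"{path}: duplicate header {header!r}")
        seen.add(header)
        taxon, seq_id = parse_header(header, separator)
        try:
            seq = Sequence(taxon=taxon, seq_id=seq_id, residues=str(rec.seq))
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
        out.append(seq)
    return out


def write_fasta(sequences: SequenceT[Sequence] | Iterable[Sequence], path) -> None:
    """Write sequences as FASTA (full seq_id as header, 60-column wrap)."""
    seqs = list(sequences)
    if not seqs:
        raise PhyloforgeError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def read_newick(path) -> GeneTree:
    """Read a single Newick tree; internal-node labels become supports."""
    with open(path) as fh:
        text = fh.read()
    return GeneTree.from_newick(text)


def write_newick(tree: GeneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
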