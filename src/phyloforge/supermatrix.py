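"""Gene-wise concatenation and occupancy reporting.

One-per-taxon gene alignments are concatenated into a partitioned
supermatrix: rows are taxa (sorted), columns are genes laid end to end in
lexicographic gene order, and a taxon absent from a gene is filled with
the missing symbol across that gene's block.  The occupancy report gives
the headline "% missing data" figure — counting both absent-taxon fill
and within-sequence gaps as missing, since both are non-observations for
inference — alongside an absence-only presence fraction per taxon x gene
block for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence as SequenceT

import pandas as pd

from phyloforge.model import Alignment, PhyloforgeError, Sequence


@dataclass
class Supermatrix:
    """Concatenated alignment with per-gene partitions."""

    taxa: list[str]
    genes: list[str]
    rows: dict[str, str]  # taxon -> concatenated residues
    gene_lengths: dict[str, int]
    fill: str = "-"

    @property
    def total_columns(self) -> int:
        return sum(self.gene_lengths[g] for g in self.genes)

    def partitions(self) -> list[tuple[str, int, int]]:
        """1-based inclusive (gene, start, end) ranges in gene order."""
        out = []
        start = 1
        for g in self.genes:
            end = start + self.gene_lengths[g] - 1
            out.append((g, start, end))
            start = end + 1
        return out

    def block(self, taxon: str, gene: str) -> str:
        for g, s, e in self.partitions():
            if g == gene:
                return self.rows[taxon][s - 1 : e]
        raise KeyError(gene)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.rows[t]}\n")

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP: names and sequences whitespace-separated."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.total_columns}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.rows[t]}\n")


@dataclass
class OccupancyReport:
    """Summary statistics of a supermatrix's completeness."""

    n_genes: int
    n_taxa: int
    total_columns: int
    percent_missing_cells: float
    percent_absent_blocks: float
    per_taxon_genes: dict[str, int] = field(default_factory=dict)
    per_gene_taxa: dict[str, int] = field(default_factory=dict)

    @property
    def percent_complete_cells(self) -> float:
        return 100.0 - self.percent_missing_cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [
                    self.n_genes,
                    self.n_taxa,
                    self.total_columns,
                    self.percent_missing_cells,
                    self.percent_complete_cells,
                    self.percent_absent_blocks,
                ]
            },
            index=[
                "n_genes",
                "n_taxa",
                "total_columns",
                "percent_missing_cells",
                "percent_complete_cells",
                "percent_absent_blocks",
            ],
        )


def concatenate(
    genes: Iterable[Alignment],
    taxon_universe: Optional[SequenceT[str]] = None,
    fill: str = "-",
) -> Supermatrix:
    """Concatenate one-per-taxon gene alignments into a supermatrix.

    Genes are ordered lexicographically by gene_id and rows by sorted
    taxon label regardless of input order; a taxon absent from a gene gets
    a block of the fill symbol.  A gene carrying two sequences for one
    taxon is an upstream contract breach and an error.
    """
    gene_list = sorted(genes, key=lambda a: a.gene_id)
    if not gene_list:
        raise PhyloforgeError("cannot concatenate zero genes")
    ids = [a.gene_id for a in gene_list]
    if len(ids) != len(set(ids)):
        raise PhyloforgeError("duplicate gene_id among genes to concatenate")
    for aln in gene_list:
        taxa = [s.taxon for s in aln.members]
        if len(taxa) != len(set(taxa)):
            raise PhyloforgeError(
                f"gene {aln.gene_id}: more than one sequence for a taxon"
            )
    if taxon_universe is None:
        universe = sorted({s.taxon for a in gene_list for s in a.members})
    else:
        universe = sorted(set(taxon_universe))
    rows = {t: [] for t in universe}
    gene_lengths = {}
    for aln in gene_list:
        gene_lengths[aln.gene_id] = aln.n_columns
        by_taxon = {s.taxon: s for s in aln.members}
        for t in universe:
            if t in by_taxon:
                rows[t].append(by_taxon[t].residues)
            else:
                rows[t].append(fill * aln.n_columns)
    return Supermatrix(
        taxa=universe,
        genes=[a.gene_id for a in gene_list],
        rows={t: "".join(parts) for t, parts in rows.items()},
        gene_lengths=gene_lengths,
        fill=fill,
    )


def partition_table(matrix: Supermatrix, model_name: str = "LG") -> str:
    """RAxML-style per-gene partition lines, e.g. ``LG, g1 = 1-100``."""
    return "\n".join(
        f"{model_name}, {g} = {s}-{e}" for g, s, e in matrix.partitions()
    )


def occupancy_stats(matrix: Supermatrix) -> OccupancyReport:
    """Missing-data percentages and per-taxon / per-gene coverage counts.

    A cell is missing when it holds the fill symbol or a gap; the
    absence-only figure counts whole taxon x gene blocks with no sequence.
    percent_missing_cells + percent_complete_cells = 100 by construction.
    """
    n_taxa = len(matrix.taxa)
    total = matrix.total_columns
    missing_chars = {matrix.fill, "-"}
    missing_cells = 0
    absent_blocks = 0
    per_taxon_genes = {t: 0 for t in matrix.taxa}
    per_gene_taxa = {g: 0 for g in matrix.genes}
    parts = matrix.partitions()
    for t in matrix.taxa:
        row = matrix.rows[t]
        missing_cells += sum(row.count(c) for c in missing_chars)
        for g, s, e in parts:
            block = row[s - 1 : e]
            if block == matrix.fill * (e - s + 1):
                absent_blocks += 1
            else:
                per_taxon_genes[t] += 1
                per_gene_taxa[g] += 1
    n_blocks = n_taxa * len(matrix.genes)
    return OccupancyReport(
        n_genes=len(matrix.genes),
        n_taxa=n_taxa,
        total_columns=total,
        percent_missing_cells=100.0 * missing_cells / (n_taxa * total),
        percent_absent_blocks=100.0 * absent_blocks / n_blocks,
        per_taxon_genes=per_taxon_genes,
        per_gene_taxa=per_gene_taxa,
    )


def compare_strategies(
    report_a: OccupancyReport,
    report_b: OccupancyReport,
    label_a: str = "strict",
    label_b: str = "distance",
) -> pd.DataFrame:
    """Side-by-side occupancy comparison of two matrices; no judgment encoded."""
    rows = ["n_genes", "n_taxa", "total_columns", "percent_missing_cells",
            "percent_complete_cells", "percent_absent_blocks"]
    a = report_a.to_frame()["value"]
    b = report_b.to_frame()["value"]
    df = pd.DataFrame({label_a: a[rows], label_b: b[rows]})
    df["delta"] = df[label_b] - df[label_a]
    taxa = sorted(set(report_a.per_taxon_genes) | set(report_b.per_taxon_genes))
    cov = pd.DataFrame(
        {
            label_a: [report_a.per_taxon_genes.get(t, 0) for t in taxa],
            label_b: [report_b.per_taxon_genes.get(t, 0) for t in taxa],
        },
        index=[f"genes_for:{t}" for t in taxa],
    )
    cov["delta"] = cov[label_b] - cov[label_a]
    return pd.concat([df, cov])
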