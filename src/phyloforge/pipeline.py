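"""Orchestration of the two supermatrix assembly strategies.

Both strategies share the front end — redundancy removal on the unaligned
sequences, then the alignment gates (length, pairwise overlap, minimum
taxa).  They differ in how one sequence per taxon is chosen:

* strict:   collapse weakly supported gene-tree nodes, keep the maximally
            inclusive subtree with at most one sequence per taxon (clades
            and shared polytomies allowed), resolve in-paralogs to the
            longest sequence;
* distance: exclude divergent sequences by nearest-other-taxon p-distance,
            then keep per taxon the sequence with the smallest mean
            p-distance to the other taxa.

Surviving genes are concatenated into a partitioned supermatrix over the
full input taxon universe, so the two strategies' occupancy figures are
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from phyloforge.distances import exclude_divergent, select_best_per_taxon
from phyloforge.gates import length_gate, min_taxa_gate, overlap_filter
from phyloforge.model import (
    Alignment,
    OrthoGroup,
    PhyloforgeError,
    PipelineConfig,
    Removal,
)
from phyloforge.pruner import UnprunableGeneError, prune_gene
from phyloforge.redundancy import remove_redundant
from phyloforge.supermatrix import (
    OccupancyReport,
    Supermatrix,
    compare_strategies,
    concatenate,
    occupancy_stats,
    partition_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one strategy run produces."""

    strategy: str
    supermatrix: Supermatrix
    occupancy: OccupancyReport
    gene_alignments: dict[str, Alignment]
    removals: dict[str, list[Removal]]
    dropped_genes: dict[str, str]
    input_counts: dict[str, int]
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def reconciles(self) -> bool:
        """input sequences = retained + removed, for every surviving gene."""
        for gid, aln in self.gene_alignments.items():
            if self.input_counts[gid] != len(aln.members) + len(self.removals[gid]):
                return False
        return True

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.supermatrix.to_fasta(out / "supermatrix.fasta")
        self.supermatrix.to_phylip(out / "supermatrix.phy")
        (out / "partitions.txt").write_text(partition_table(self.supermatrix) + "\n")
        self.occupancy.to_frame().to_csv(out / "occupancy.tsv", sep="\t")
        with open(out / "removals.tsv", "w") as fh:
            fh.write("gene_id\tstage\tseq_id\treason\n")
            for gid in sorted(self.removals):
                for r in self.removals[gid]:
                    fh.write(f"{gid}\t{r.stage}\t{r.seq_id}\t{r.reason}\n")
        with open(out / "dropped_genes.tsv", "w") as fh:
            fh.write("gene_id\treason\n")
            for gid in sorted(self.dropped_genes):
                fh.write(f"{gid}\t{self.dropped_genes[gid]}\n")


def load_orthogroups(input_dir, config: Optional[PipelineConfig] = None) -> list[OrthoGroup]:
    """Load per-gene inputs from a directory.

    Expects ``<gene>.aln.fasta`` (aligned, required), ``<gene>.fasta``
    (unaligned, optional — derived by degapping if absent) and
    ``<gene>.nwk`` (gene tree, optional but required by the strict
    strategy).
    """
    from phyloforge.io import read_fasta, read_newick

    config = config or PipelineConfig()
    indir = Path(input_dir)
    genes = []
    for aln_path in sorted(indir.glob("*.aln.fasta")):
        gene_id = aln_path.name[: -len(".aln.fasta")]
        members = read_fasta(aln_path, config.header_separator)
        alignment = Alignment(gene_id, members)
        una_path = indir / f"{gene_id}.fasta"
        if una_path.exists():
            unaligned = read_fasta(una_path, config.header_separator)
        else:
            unaligned = [s.with_residues(s.ungapped()) for s in members]
        nwk_path = indir / f"{gene_id}.nwk"
        tree = read_newick(nwk_path) if nwk_path.exists() else None
        genes.append(
            OrthoGroup(gene_id=gene_id, unaligned=unaligned, alignment=alignment, tree=tree)
        )
    if not genes:
        raise PhyloforgeError(f"no *.aln.fasta orthogroups found in {input_dir}")
    return genes


def _front_end(
    og: OrthoGroup, config: PipelineConfig
) -> tuple[Optional[Alignment], list[Removal], Optional[str]]:
    """Shared stages: redundancy, length gate, overlap filter, taxon gate.

    Returns (alignment, removals, drop_reason); alignment is None when the
    whole gene is discarded.
    """
    removals: list[Removal] = []
    if og.alignment is None:
        return None, removals, "no-alignment"
    aln = og.alignment
    unaligned = og.unaligned or [s.with_residues(s.ungapped()) for s in aln.members]
    _, red = remove_redundant(unaligned)
    removals.extend(red)
    redundant_ids = {r.seq_id for r in red}
    aln = aln.subset(s.seq_id for s in aln.members if s.seq_id not in redundant_ids)
    if not length_gate(aln, config.min_alignment_columns):
        return None, removals, f"alignment-shorter-than-{config.min_alignment_columns}"
    aln, ov = overlap_filter(aln, config.min_pairwise_overlap)
    removals.extend(ov)
    if not aln.members:
        return None, removals, "no-sequences-after-overlap-filter"
    if not min_taxa_gate(aln, config.min_taxa_per_gene):
        return None, removals, f"fewer-than-{config.min_taxa_per_gene}-taxa"
    return aln, removals, None


def _run(
    genes: list[OrthoGroup], config: PipelineConfig, strategy: str
) -> PipelineResult:
    universe = sorted(
        {
            s.taxon
            for og in genes
            for s in (og.alignment.members if og.alignment else og.unaligned)
        }
    )
    final: dict[str, Alignment] = {}
    removals: dict[str, list[Removal]] = {}
    dropped: dict[str, str] = {}
    input_counts: dict[str, int] = {}
    for og in sorted(genes, key=lambda g: g.gene_id):
        gid = og.gene_id
        input_counts[gid] = len(og.alignment.members if og.alignment else og.unaligned)
        aln, log, reason = _front_end(og, config)
        if reason is not None:
            dropped[gid] = reason
            logger.info("gene %s dropped: %s", gid, reason)
            continue
        try:
            if strategy == "strict":
                stage_og = OrthoGroup(
                    gene_id=gid, alignment=aln, tree=og.tree, unaligned=None
                )
                pruned = prune_gene(stage_og, config)
                log.extend(pruned.removed)
                aln = aln.subset(s.seq_id for s in pruned.retained)
            elif strategy == "distance":
                aln, div = exclude_divergent(aln, config.divergence_threshold)
                log.extend(div)
                if not aln.members:
                    dropped[gid] = "no-sequences-after-divergence-filter"
                    continue
                aln, sel = select_best_per_taxon(aln)
                log.extend(sel)
            else:
                raise ValueError(f"unknown strategy {strategy!r}")
        except (UnprunableGeneError, PhyloforgeError) as exc:
            dropped[gid] = f"skip:{exc}"
            logger.info("gene %s skipped: %s", gid, exc)
            continue
        if not min_taxa_gate(aln, config.min_taxa_per_gene):
            dropped[gid] = f"fewer-than-{config.min_taxa_per_gene}-taxa-after-{strategy}"
            continue
        final[gid] = aln
        removals[gid] = log
    if not final:
        raise PhyloforgeError(f"{strategy} strategy produced an empty supermatrix")
    sm = concatenate(final.values(), taxon_universe=universe, fill=config.missing_fill_symbol)
    occ = occupancy_stats(sm)
    return PipelineResult(
        strategy=strategy,
        supermatrix=sm,
        occupancy=occ,
        gene_alignments=final,
        removals=removals,
        dropped_genes=dropped,
        input_counts=input_counts,
        config=config,
    )


def run_strict(genes: list[OrthoGroup], config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Redundancy -> gates -> tree-based pruning -> taxon gate -> supermatrix."""
    return _run(genes, config or PipelineConfig(), "strict")


def run_distance(genes: list[OrthoGroup], config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Redundancy -> gates -> divergence exclusion -> best-per-taxon -> supermatrix."""
    return _run(genes, config or PipelineConfig(), "distance")


def run_both(genes: list[OrthoGroup], config: Optional[PipelineConfig] = None):
    """Run both strategies on identical inputs; return both results + comparison."""
    config = config or PipelineConfig()
    strict = run_strict(genes, config)
    distance = run_distance(genes, config)
    table = compare_strategies(strict.occupancy, distance.occupancy)
    return strict, distance, table
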