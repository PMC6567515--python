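# Methods

## Pipeline model

The unit of processing is the orthogroup ("gene"): a set of amino-acid
sequences across taxa inferred to descend from one ancestral gene, with
the taxon encoded in each FASTA header before a separator (default `@`;
the sequence id is the full header, so ids are globally unique and gene
trees can reference them directly). Genes flow through:

1. **Redundancy removal** (unaligned): within each taxon, a sequence
   identical to — or a contiguous substring of — a retained sequence is
   removed. Containment on ungapped residues operationalizes "identical
   where they overlap": transcript fragments are contiguous, so partial
   sequences identical to part of a longer one are substrings of it;
   partial overlaps with mismatches are kept. Comparison is within taxon
   only: a conserved gene may legitimately be identical across related
   species. `X` matches strictly. Processing order is decreasing ungapped
   length then seq_id, so the longest representative survives and exact
   ties retain the smaller id.
2. **Alignment gates**: alignments shorter than `min_alignment_columns`
   (default 50; the unit is alignment columns — the data are proteins) are
   discarded; then, while any pair of sequences shares fewer than
   `min_pairwise_overlap` (default 20) residue-bearing columns, the
   shortest sequence failing the overlap-with-all-others criterion is
   deleted and the failing set recomputed after every single removal
   (per-removal recomputation matches the sequential "starting with the
   shortest" rule and is deterministic; ties delete the lexicographically
   larger id). `X` counts as a residue for overlap — it occupies a
   position. Finally genes with fewer than `min_taxa_per_gene` (default
   10) distinct taxa are discarded. Removing a sequence never decreases a
   remaining pair's overlap, which justifies the greedy loop.
3. **Selection** — one of two strategies (below).
4. **Concatenation**: genes ordered lexicographically, rows ordered by
   taxon label, absent taxon × gene blocks filled with `-` (configurable
   to `?`); a RAxML-style partition table (`LG, gene = start-end`,
   1-based inclusive) and an occupancy report are emitted.

## Strict strategy (tree-based pruning)

Consumes one unrooted gene tree per gene with supports on internal edges
(both the 0–1 and 0–100 Newick dialects are accepted; if any parsed
support exceeds 1 all are divided by 100, an idempotent rule). Steps:

* **Collapse**: every internal edge with support `< support_collapse_threshold`
  (default 0.95, strictly below) is contracted into a polytomy. Edges
  with *absent* support are collapsed too — conservative, since an
  unlabelled edge carries no evidence.
* **Selection**: the candidate subtrees of an unrooted tree are exactly
  the full leaf set plus the two leaf sets obtained by cutting each edge.
  A candidate is valid when every taxon with ≥ 2 leaves inside it either
  forms a clade in the unrooted sense (some edge cut of the candidate
  separates exactly that taxon's leaves — including the case where they
  are the complement of the cut side) or hangs off one common node (same
  polytomy). Among valid candidates the winner maximizes, in order:
  distinct taxa, leaf count, total ungapped length, then the
  lexicographically smallest sorted leaf tuple. Taxon count leads because
  matrix occupancy is the quantity at stake; the full tie-break chain
  makes pruning deterministic. Genes with no valid candidate spanning two
  taxa are flagged unprunable and dropped, not guessed.
* **Resolution**: inside the selected subtree each multi-copy taxon keeps
  its longest (ungapped) sequence, ties to the smaller id.

When the gene tree carries leaves already removed by earlier stages, the
tree is restricted to the surviving leaves first; merging edges while
suppressing a degree-2 node assigns the merged edge the minimum of the
present supports (conservative) and the sum of branch lengths.

The implementation is verified against an independent brute-force oracle
(exhaustive leaf-subset enumeration, edge-cut realizability and clade
tests via Steiner-subtree disjointness, same tie-break) on 1,000 random
collapsed trees with up to 12 leaves; agreement is exact.

## Distance strategy (p-distance selection)

* **Divergence exclusion**: a sequence is removed when its minimum
  p-distance to any sequence of a different taxon exceeds
  `divergence_threshold` (default 0.25). A genuine ortholog has a near
  neighbour in some related taxon; a foreign contaminant does not.
  Single-taxon genes pass unchanged. The threshold is a config knob
  standing in for an external tool's "default settings", and is echoed in
  all logs.
* **Best per taxon**: each taxon keeps the candidate minimizing the mean
  p-distance to sequences of *other* taxa — own duplicates are excluded
  from the average so they cannot vote for each other. Ties go to the
  longer sequence, then the smaller id. No chimeric merging of
  non-overlapping same-taxon fragments is performed: one whole sequence
  is always chosen.

p-distance: mismatches over comparable columns, where a column is
comparable if both sequences have a non-gap, non-`X` character. Zero
comparable columns gives distance 1.0 with a logged warning.

## Occupancy accounting

`percent_missing_cells` counts both absent-taxon fill and within-sequence
gaps, since a headline "% missing data" figure on a concatenated matrix
necessarily includes alignment gaps; the absence-only fraction of empty
taxon × gene blocks is reported alongside for transparency, and `X` counts
as present (it is a residue observation). By construction
`percent_missing + percent_complete = 100` exactly, and per-gene
missingness aggregates exactly to matrix missingness weighted by gene
length.

## The simulator

The generator emulates the statistical structure the pipeline assumes and
the pathologies it must survive, with per-sequence ground-truth labels:

* A species tree is built by sequential random joins (branch lengths
  uniform per join) and rescaled to unit root-to-tip depth, so
  substitution rates are per unit depth. Default `substitution_rate` 0.1
  keeps within-gene p-distances of genuine orthologs well under the 0.25
  divergence threshold while leaving measurable signal — typical of
  conserved core-ortholog sets.
* Sequences evolve site-independently: per-site substitution counts are
  Poisson(rate × branch length); each substitution moves to a uniformly
  drawn different residue. No indels, so the true alignment is the tip
  set itself. Defaults: 20 taxa, 200 genes, 300 aa root length (typical
  gene-wise averages for transcriptome-scale supermatrices).
* Pathologies, applied per gene in fixed order, each planting one event:
  taxon **dropout** (Bernoulli per taxon, default 0.3 — the occupancy
  control); an **in-paralog** (tip duplicated with extra divergence drawn
  from 0.2–0.6 units on a short branch); an **out-paralog** (a uniformly
  chosen internal edge's subtree re-evolved from its ancestral sequence
  off a 0.8-unit stem, then the *original* copy lost per affected taxon
  with probability 0.5 — duplication followed by differential loss, the
  mechanism that makes tree-based pruning genuinely lossy rather than
  merely duplicate-trimming); a **contaminant** (a donor taxon's sequence
  evolved 0.05 units and relabelled with a different acceptor taxon, so
  it attaches inside the donor's lineage); a **fragment** (a contiguous
  window of 0.3–0.7 of the sequence, terminal gaps elsewhere).
* Supports are simulated labels, not bootstrap computations: each
  internal edge is weak (drawn from [0.3, 0.95)) with probability
  `weak_support_prob`, else strong ([0.95, 1.0]). The pruner consumes
  supports as given, so nothing is lost by not computing them.
* Determinism: gene *i* uses an rng seeded from `(rng_seed, i)`; reruns
  are byte-identical.

What the simulator does **not** model — indels and alignment error,
rate heterogeneity across sites and lineages, empirical exchangeability
matrices, biased codon usage, assembly chimeras, correlated dropout —
bounds what passing tests show: they validate the selection, pruning and
book-keeping logic under known truth, not robustness to alignment or
tree-estimation error on real data (trees are inputs here, as in the
pipeline itself).

## Problem sizes and numerical choices

The end-to-end strategy-contrast experiments use 50-replicate batches of
50 genes × 30 taxa × 300 aa with dropout 0.1, in-paralogs 0.2,
out-paralogs 0.4 (loss 0.5), contaminants 0.3, fragments 0.1 and weak
supports 0.15 — sizes chosen so each batch completes in a couple of
minutes on one CPU while every event type appears many times per
replicate. Thirty taxa (rather than the simulator's default 20) keep
heavily pruned genes above the 10-taxon gate, so the completeness
comparison reflects within-gene sequence loss rather than which genes
happen to be discarded. All tie-breaks (redundancy, overlap deletion,
subtree selection, in-paralog and best-per-taxon resolution) are
specified exactly and make every stage deterministic for fixed inputs;
stage logs record each removal with its rule, and
input = retained + removed holds per gene at every stage.

## Known limitations

* The redundancy step is exact-containment only; near-identical
  haplotypes (< 100% identity) are all retained, as in the modelled
  protocol — clustering at lower identity is out of scope.
* The strict pruner considers single-edge cuts (the subtrees of an
  unrooted tree); it does not attempt multi-cut decompositions, rooting
  by outgroup, or duplication/loss reconciliation.
* A contaminant for a taxon otherwise absent from a gene is invisible to
  both strategies (it is the taxon's only representative and forms no
  duplicate pair) — a genuine property of both modelled tools, not a bug.
* The distance strategy's divergence threshold is a raw p-distance; no
  model correction (Poisson/Gamma) is applied.
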