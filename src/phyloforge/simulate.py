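"""Gene-family simulation with planted pathologies and ground truth.

Generates per-gene orthogroups (true alignments plus true gene trees with
simulated support values) by evolving amino-acid sequences down a random
species tree, then planting the data problems a supermatrix pipeline must
handle: per-gene taxon dropout (controlling matrix occupancy),
lineage-specific duplications (in-paralogs, a short extra branch),
ancient duplications (out-paralogs, a second copy of a whole subtree
hanging off a long stem, with per-taxon loss of the original copy —
duplication followed by differential loss is what makes tree-based
orthology screening genuinely lossy), cross-taxon contamination (a
near-clone of a donor taxon's sequence mislabelled with an acceptor
taxon), and fragmentary transcripts (contiguous windows with terminal
gaps).

Sequences evolve site-independently: the substitution count per site on a
branch is Poisson(rate x branch length) and each substitution replaces
the residue with a uniformly drawn different amino acid.  No indels are
simulated, so the true alignment is the aligned set of tip sequences with
gaps only at fragment ends.  Supports are simulated labels (strong or
weak, drawn per edge), not bootstrap computations: the pruner consumes
supports as given.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from phyloforge.model import AMINO_ACIDS, Alignment, OrthoGroup, Sequence
from phyloforge.tree import GeneTree

_N_AA = 20


@dataclass
class SimParams:
    """Simulation conditions.

    Rates are expressed in expected substitutions per site per unit of
    species-tree depth (the tree is scaled so the deepest root-to-tip
    path is 1).  The pathology probabilities are per gene: an affected
    gene receives exactly one event of that kind.
    """

    n_taxa: int = 20
    n_genes: int = 200
    root_sequence_length: int = 300
    substitution_rate: float = 0.1
    dropout_prob: float = 0.3
    inparalog_prob: float = 0.1
    outparalog_prob: float = 0.1
    contaminant_prob: float = 0.1
    fragment_prob: float = 0.1
    fragment_fraction_range: tuple[float, float] = (0.3, 0.7)
    weak_support_prob: float = 0.1
    support_strong_range: tuple[float, float] = (0.95, 1.0)
    support_weak_range: tuple[float, float] = (0.3, 0.95)
    inparalog_extra_range: tuple[float, float] = (0.2, 0.6)
    outparalog_stem: float = 0.8
    postduplication_loss_prob: float = 0.5
    contaminant_branch: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "inparalog_prob", "outparalog_prob",
                     "contaminant_prob", "fragment_prob", "weak_support_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_taxa < 2 or self.n_genes < 1 or self.root_sequence_length < 1:
            raise ValueError("sizes must be positive (n_taxa >= 2)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GeneTruth:
    gene_id: str
    labels: dict[str, str]  # seq_id -> ortholog/inparalog/outparalog/contaminant/...
    tree_newick: str


@dataclass
class SimTruth:
    species_tree_newick: str
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def label(self, gene_id: str, seq_id: str) -> str:
        return self.genes[gene_id].labels[seq_id]


# --------------------------------------------------------------------- #
# species tree


@dataclass
class _Node:
    branch: float
    children: list["_Node"] = field(default_factory=list)
    taxon: Optional[str] = None
    seq_id: Optional[str] = None
    seq: Optional[np.ndarray] = None

    def is_leaf(self) -> bool:
        return not self.children

    def tips(self) -> list["_Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


class SpeciesTree:
    """A rooted binary species tree with unit-scaled depth."""

    def __init__(self, root: _Node) -> None:
        self.root = root

    @property
    def n_leaves(self) -> int:
        return len(self.root.tips())

    def leaf_names(self) -> list[str]:
        return sorted(t.taxon for t in self.root.tips())

    @property
    def n_internal_edges(self) -> int:
        def count(node: _Node, is_root: bool) -> int:
            n = 0 if (is_root or node.is_leaf()) else 1
            return n + sum(count(c, False) for c in node.children)

        return count(self.root, True)

    def newick(self) -> str:
        def fmt(node: _Node) -> str:
            if node.is_leaf():
                return f"{node.taxon}:{node.branch:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.branch:.6f}"

        return fmt(self.root)[: -len(f":{self.root.branch:.6f}")] + ";"


def simulate_species_tree(n_taxa: int, seed: int) -> SpeciesTree:
    """Random binary tree by sequential random joins, scaled to unit depth.

    Branch lengths are drawn uniformly per join and the whole tree is
    rescaled so the deepest root-to-tip path equals 1; substitution rates
    are then per unit depth.  Deterministic under the seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_taxa)))
    clusters = [
        _Node(branch=0.0, taxon=f"t{i + 1:0{width}d}") for i in range(n_taxa)
    ]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        a.branch = float(rng.uniform(0.5, 1.5))
        b.branch = float(rng.uniform(0.5, 1.5))
        parent = _Node(branch=0.0, children=[a, b])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(parent)
    root = clusters[0]

    def depth(node: _Node) -> float:
        if node.is_leaf():
            return node.branch
        return node.branch + max(depth(c) for c in node.children)

    scale = depth(root)

    def rescale(node: _Node) -> None:
        node.branch /= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    return SpeciesTree(root)


# --------------------------------------------------------------------- #
# sequence evolution


def _evolve(seq: np.ndarray, branch: float, rate: float, rng) -> np.ndarray:
    out = seq.copy()
    hits = rng.poisson(rate * branch, size=len(seq))
    for i in np.nonzero(hits)[0]:
        for _ in range(hits[i]):
            out[i] = (out[i] + rng.integers(1, _N_AA)) % _N_AA
    return out


def _to_letters(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def _copy_subtree(node: _Node) -> _Node:
    return _Node(
        branch=node.branch,
        children=[_copy_subtree(c) for c in node.children],
        taxon=node.taxon,
        seq_id=node.seq_id,
        seq=None if node.seq is None else node.seq.copy(),
    )


# --------------------------------------------------------------------- #
# one gene


def simulate_gene(
    species_tree: SpeciesTree,
    params: SimParams,
    gene_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[OrthoGroup, GeneTruth]:
    """Evolve one gene down the species tree and plant pathologies.

    With all pathology probabilities zero and dropout zero, the result is
    exactly one full-length sequence per taxon whose gene-tree topology
    equals the species topology.  Returns the orthogroup (unaligned and
    aligned sequences plus the true gene tree with simulated supports)
    and the per-sequence truth labels.
    """
    if rng is None:
        rng = np.random.default_rng([params.rng_seed, gene_index])
    gene_id = f"g{gene_index:04d}"
    rate = params.substitution_rate
    L = params.root_sequence_length

    # 1. evolve the ortholog copy down the species tree
    def grow(snode: _Node, seq: np.ndarray) -> _Node:
        new_seq = _evolve(seq, snode.branch, rate, rng)
        node = _Node(branch=snode.branch, seq=new_seq, taxon=snode.taxon)
        if snode.is_leaf():
            node.seq_id = f"{snode.taxon}@{gene_id}"
        else:
            node.children = [grow(c, new_seq) for c in snode.children]
        return node

    root_seq = rng.integers(0, _N_AA, size=L)
    groot = grow(species_tree.root, root_seq)
    labels: dict[str, str] = {t.seq_id: "ortholog" for t in groot.tips()}

    # 2. dropout, conditioned on at least one surviving taxon
    all_taxa = species_tree.leaf_names()
    if params.dropout_prob >= 1.0:
        dropped = set(all_taxa) - {str(rng.choice(all_taxa))}
    else:
        while True:
            dropped = {t for t in all_taxa if rng.random() < params.dropout_prob}
            if len(dropped) < len(all_taxa):
                break

    def prune(node: _Node) -> Optional[_Node]:
        if node.is_leaf():
            return None if node.taxon in dropped else node
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress unary node, absorbing the branch
            kids[0].branch += node.branch
            return kids[0]
        node.children = kids
        return node

    groot = prune(groot)
    for taxon in dropped:
        labels.pop(f"{taxon}@{gene_id}", None)
    survivors = sorted(t.taxon for t in groot.tips())

    def find_tip(taxon: str) -> _Node:
        return next(t for t in groot.tips() if t.taxon == taxon and t.seq_id)

    # 3. one in-paralog: duplicate a tip with extra divergence on a short branch
    if rng.random() < params.inparalog_prob and survivors:
        taxon = str(rng.choice(survivors))
        tip = find_tip(taxon)
        extra = float(rng.uniform(*params.inparalog_extra_range))
        copy = _Node(
            branch=extra,
            taxon=taxon,
            seq_id=f"{taxon}@{gene_id}_i",
            seq=_evolve(tip.seq, extra, rate, rng),
        )
        labels[copy.seq_id] = "inparalog"
        _split_tip(tip, copy)

    # 4. one out-paralog: re-evolve a duplicated subtree from an internal
    #    edge, then lose the original copy for some of the affected taxa
    #    (duplication + differential loss)
    if rng.random() < params.outparalog_prob:
        internals = _internal_children(groot)
        if internals:
            idx = int(rng.integers(len(internals)))
            parent, child = internals[idx]
            dup = _copy_subtree(child)
            dup.branch = params.outparalog_stem

            def reevolve(node: _Node, seq: np.ndarray) -> None:
                node.seq = _evolve(seq, node.branch, rate, rng)
                if node.is_leaf():
                    node.seq_id = f"{node.seq_id}_p"
                    labels[node.seq_id] = "outparalog"
                for c in node.children:
                    reevolve(c, node.seq)

            reevolve(dup, child.seq)
            joint = _Node(branch=child.branch, children=[child, dup], seq=child.seq)
            child.branch = 0.01
            parent.children[parent.children.index(child)] = joint
            affected = sorted({t.taxon for t in dup.tips()})
            for taxon in affected:
                if rng.random() < params.postduplication_loss_prob:
                    orig_id = f"{taxon}@{gene_id}"
                    if orig_id in labels:
                        groot = _remove_leaf(groot, orig_id)
                        labels.pop(orig_id)

    # 5. one contaminant: clone a donor sequence, relabel with an acceptor
    if rng.random() < params.contaminant_prob and len(survivors) >= 2:
        donor, acceptor = (
        str(x) for x in rng.choice(survivors, size=2, replace=False)
        )
        tip = find_tip(donor)
        contam = _Node(
            branch=params.contaminant_branch,
            taxon=acceptor,
            seq_id=f"{acceptor}@{gene_id}_c",
            seq=_evolve(tip.seq, params.contaminant_branch, rate, rng),
        )
        labels[contam.seq_id] = "contaminant"
        _split_tip(tip, contam)

    # 6. one fragment: truncate a tip to a contiguous window
    tips = sorted(groot.tips(), key=lambda t: t.seq_id)
    if rng.random() < params.fragment_prob:
        victim = tips[int(rng.integers(len(tips)))]
        frac = float(rng.uniform(*params.fragment_fraction_range))
        flen = max(1, round(frac * L))
        start = int(rng.integers(0, L - flen + 1))
        mask = np.zeros(L, dtype=bool)
        mask[start : start + flen] = True
        victim.seq = np.where(mask, victim.seq, -1)  # -1 marks a terminal gap
        labels[victim.seq_id] = f"fragment-of-{labels[victim.seq_id]}"

    # 7. emit alignment, unaligned sequences, and the support-labelled tree
    members = []
    for t in sorted(groot.tips(), key=lambda t: t.seq_id):
        residues = "".join(
            "-" if i < 0 else AMINO_ACIDS[i] for i in t.seq
        )
        members.append(Sequence(taxon=t.taxon, seq_id=t.seq_id, residues=residues))
    alignment = Alignment(gene_id, members)
    unaligned = [s.with_residues(s.ungapped()) for s in members]
    tree = _to_gene_tree(groot, params, rng) if len(members) >= 2 else None
    truth = GeneTruth(
        gene_id=gene_id,
        labels=dict(labels),
        tree_newick=tree.to_newick() if tree is not None else "",
    )
    og = OrthoGroup(gene_id=gene_id, unaligned=unaligned, alignment=alignment, tree=tree)
    return og, truth


def _split_tip(tip: _Node, new_leaf: _Node) -> None:
    """Turn a tip into a cherry: the original (short branch) plus a new leaf."""
    original = _Node(branch=0.01, taxon=tip.taxon, seq_id=tip.seq_id, seq=tip.seq)
    tip.children = [original, new_leaf]
    tip.seq_id = None
    tip.taxon = None


def _remove_leaf(node: _Node, seq_id: str) -> Optional[_Node]:
    """Delete one tip, suppressing the unary node it leaves behind."""
    if node.is_leaf():
        return None if node.seq_id == seq_id else node
    node.children = [
        k for k in (_remove_leaf(c, seq_id) for c in node.children) if k is not None
    ]
    if not node.children:
        return None
    if len(node.children) == 1:
        node.children[0].branch += node.branch
        return node.children[0]
    return node


def _internal_children(root: _Node) -> list[tuple[_Node, _Node]]:
    out = []

    def walk(node: _Node) -> None:
        for c in node.children:
            if not c.is_leaf():
                out.append((node, c))
                walk(c)

    walk(root)
    return out


def _to_gene_tree(root: _Node, params: SimParams, rng) -> GeneTree:
    """Convert the rooted simulation tree to an unrooted GeneTree.

    Each internal edge receives a simulated support: weak (drawn from the
    weak range) with probability weak_support_prob, strong otherwise.
    """
    adjacency: dict[int, set[int]] = {}
    leaf_label: dict[int, str] = {}
    supports: dict[frozenset, Optional[float]] = {}
    lengths: dict[frozenset, float] = {}
    counter = [0]

    def walk(node: _Node, parent_id: Optional[int]) -> None:
        nid = counter[0]
        counter[0] += 1
        adjacency[nid] = set()
        if node.is_leaf():
            leaf_label[nid] = node.seq_id
        if parent_id is not None:
            adjacency[nid].add(parent_id)
            adjacency[parent_id].add(nid)
            e = frozenset((nid, parent_id))
            lengths[e] = node.branch
            if not node.is_leaf():
                if rng.random() < params.weak_support_prob:
                    supports[e] = float(rng.uniform(*params.support_weak_range))
                else:
                    supports[e] = float(rng.uniform(*params.support_strong_range))
        for c in node.children:
            walk(c, nid)

    walk(root, None)
    return GeneTree(adjacency, leaf_label, supports, lengths, root=0)


# --------------------------------------------------------------------- #
# whole dataset


def simulate_dataset(
    params: SimParams,
) -> tuple[list[OrthoGroup], SimTruth, dict]:
    """Simulate ``n_genes`` independent genes on one species tree.

    The manifest records the seed and every parameter; reruns with the
    same params are byte-identical (each gene uses an rng seeded from
    (rng_seed, gene_index)).
    """
    stree = simulate_species_tree(params.n_taxa, params.rng_seed)
    truth = SimTruth(species_tree_newick=stree.newick())
    genes: list[OrthoGroup] = []
    for gi in range(params.n_genes):
        og, gt = simulate_gene(stree, params, gi)
        genes.append(og)
        truth.genes[og.gene_id] = gt
    manifest = {"rng_seed": params.rng_seed, **params.to_dict()}
    return genes, truth, manifest


def write_dataset(
    genes: list[OrthoGroup], truth: SimTruth, manifest: dict, outdir
) -> None:
    """Write per-gene aligned/unaligned FASTA + Newick, a truth table, a manifest."""
    from phyloforge.io import write_fasta, write_newick

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for og in genes:
        write_fasta(og.alignment.members, out / f"{og.gene_id}.aln.fasta")
        write_fasta(og.unaligned, out / f"{og.gene_id}.fasta")
        if og.tree is not None:
            write_newick(og.tree, out / f"{og.gene_id}.nwk")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("gene_id\tseq_id\tlabel\n")
        for gid in sorted(truth.genes):
            for sid in sorted(truth.genes[gid].labels):
                fh.write(f"{gid}\t{sid}\t{truth.genes[gid].labels[sid]}\n")
    with open(out / "species_tree.nwk", "w") as fh:
        fh.write(truth.species_tree_newick + "\n")
    with open(out / "manifest.txt", "w") as fh:
        for k in sorted(manifest):
            fh.write(f"{k} = {manifest[k]}\n")
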