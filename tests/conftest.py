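import numpy as np
import pytest

from phyloforge.model import Alignment, Sequence
from phyloforge.tree import GeneTree


def mkseq(taxon: str, sid: str, residues: str) -> Sequence:
    return Sequence(taxon=taxon, seq_id=sid, residues=residues)


def mkaln(gene_id: str, rows: dict[str, str], sep: str = "@") -> Alignment:
    """rows maps seq_id ('taxon@rest') to residues."""
    return Alignment(
        gene_id,
        [mkseq(sid.split(sep, 1)[0], sid, res) for sid, res in rows.items()],
    )


def build_random_tree(
    rng: np.random.Generator, n_leaves: int, n_taxa: int | None = None
) -> tuple[GeneTree, dict[str, str], dict[str, int]]:
    """Random unrooted binary tree with random supports and taxon multiplicities.

    Supports are absent with probability 0.2, otherwise uniform in [0, 1],
    so collapsing at 0.95 yields trees with realistic polytomies.  Returns
    the tree, the seq_id -> taxon map, and random ungapped lengths.
    """
    n_taxa = n_taxa or max(2, n_leaves // 2)
    taxon_of = {}
    labels = []
    for i in range(n_leaves):
        t = f"T{int(rng.integers(1, n_taxa + 1))}"
        lab = f"{t}@s{i}"
        labels.append(lab)
        taxon_of[lab] = t
    adjacency: dict[int, set[int]] = {i: set() for i in range(n_leaves)}
    leaf_label = dict(enumerate(labels))
    supports: dict[frozenset, float | None] = {}
    clusters = list(range(n_leaves))
    nxt = n_leaves
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        adjacency[nxt] = {a, b}
        adjacency[a].add(nxt)
        adjacency[b].add(nxt)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [nxt]
        nxt += 1
    a, b = clusters
    adjacency[a].add(b)
    adjacency[b].add(a)
    # supports on internal edges only
    seen = set()
    for u, vs in adjacency.items():
        for v in vs:
            e = frozenset((u, v))
            if e in seen or u in leaf_label or v in leaf_label:
                continue
            seen.add(e)
            supports[e] = None if rng.random() < 0.2 else float(rng.uniform(0, 1))
    tree = GeneTree(adjacency, leaf_label, supports)
    lengths = {lab: int(rng.integers(50, 300)) for lab in labels}
    return tree, taxon_of, lengths


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
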