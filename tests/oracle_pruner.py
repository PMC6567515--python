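"""Independent brute-force oracle for the subtree-selection step.

Enumerates every leaf subset of an unrooted tree, keeps those realizable
by a single edge cut, tests the one-per-taxon validity rule directly, and
applies the published tie-break chain.  Realizability and clade tests use
Steiner-tree disjointness (the minimal connecting subgraphs of a subset
and of its complement share no node iff the subset is one side of an
edge cut), a mechanism deliberately different from the implementation's
side-of-edge enumeration.
"""

from __future__ import annotations

from itertools import combinations


def steiner_nodes(adjacency: dict[int, set[int]], terminals: set[int]) -> set[int]:
    """Nodes of the minimal subtree connecting ``terminals``.

    Works by repeatedly trimming non-terminal nodes of degree <= 1 from a
    working copy of the tree.
    """
    deg = {u: len(vs) for u, vs in adjacency.items()}
    alive = set(adjacency)
    changed = True
    while changed:
        changed = False
        for u in list(alive):
            if u not in terminals and deg[u] <= 1:
                alive.discard(u)
                for v in adjacency[u]:
                    if v in alive:
                        deg[v] -= 1
                deg[u] = 0
                changed = True
    return alive


def realizable_subsets(tree) -> list[frozenset[str]]:
    """All leaf subsets (size >= 2) that are one side of a single edge cut."""
    labels = sorted(tree.leaves())
    node_of = {lab: tree.node_of_leaf(lab) for lab in labels}
    full = frozenset(labels)
    out = [full]
    for k in range(2, len(labels)):
        for combo in combinations(labels, k):
            s = set(combo)
            comp = set(labels) - s
            st_s = steiner_nodes(tree.adjacency, {node_of[l] for l in s})
            st_c = steiner_nodes(tree.adjacency, {node_of[l] for l in comp})
            if not (st_s & st_c):
                out.append(frozenset(s))
    return out


def subset_valid(tree, cand: frozenset[str], taxon_of: dict[str, str]) -> bool:
    """One-per-taxon rule checked by Steiner disjointness + shared attachment."""
    node_of = {lab: tree.node_of_leaf(lab) for lab in cand}
    by_taxon: dict[str, set[str]] = {}
    for lab in cand:
        by_taxon.setdefault(taxon_of[lab], set()).add(lab)
    for group in by_taxon.values():
        if len(group) < 2 or group == cand:
            continue
        rest = cand - group
        st_g = steiner_nodes(tree.adjacency, {node_of[l] for l in group})
        st_r = steiner_nodes(tree.adjacency, {node_of[l] for l in rest})
        if not (st_g & st_r):
            continue  # clade within the candidate
        attach = {next(iter(tree.adjacency[node_of[l]])) for l in group}
        if len(attach) == 1:
            continue  # same polytomy
        return False
    return True


def best_subtree_bruteforce(
    tree, taxon_of: dict[str, str], lengths: dict[str, int]
):
    """Exhaustive reference for select_maximal_subtree; None if unprunable."""
    best = None
    best_key = None
    for cand in realizable_subsets(tree):
        if len({taxon_of[l] for l in cand}) < 2:
            continue
        if not subset_valid(tree, cand, taxon_of):
            continue
        key = (
            len({taxon_of[l] for l in cand}),
            len(cand),
            sum(lengths.get(l, 0) for l in cand),
        )
        names = tuple(sorted(cand))
        if best is None or key > best_key[0] or (key == best_key[0] and names < best_key[1]):
            best, best_key = cand, (key, names)
    return best
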