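"""Unrooted gene trees with per-internal-edge support values.

A gene tree is stored as an undirected graph: integer nodes, an adjacency
map, leaf labels, and a support value (possibly absent) on every internal
edge (an edge whose endpoints are both internal nodes).  Support values are
normalized to [0, 1]; trees labelled in the 0-100 percentage dialect are
detected by the presence of any value > 1 and rescaled.

Newick parsing and serialization go through dendropy; the graph form is
what the paralogy pruner manipulates (edge contraction, edge-cut leaf-set
enumeration, clade and polytomy tests).
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

from phyloforge.model import NewickParseError

Edge = frozenset  # frozenset of two node ids


class GeneTree:
    """An unrooted tree over sequence labels with supports on internal edges."""

    def __init__(
        self,
        adjacency: dict[int, set[int]],
        leaf_label: dict[int, str],
        supports: dict[Edge, Optional[float]],
        lengths: Optional[dict[Edge, float]] = None,
        root: Optional[int] = None,
    ) -> None:
        self.adjacency = {u: set(vs) for u, vs in adjacency.items()}
        self.leaf_label = dict(leaf_label)
        self.supports = dict(supports)
        self.lengths = dict(lengths) if lengths else {}
        if root is None:
            internal = [u for u in self.adjacency if u not in self.leaf_label]
            root = internal[0] if internal else next(iter(self.adjacency))
        self.root = root
        self._validate()

    # ------------------------------------------------------------------ #
    # construction / validation

    def _validate(self) -> None:
        for u, vs in self.adjacency.items():
            for v in vs:
                if u not in self.adjacency.get(v, ()):
                    raise ValueError("adjacency is not symmetric")
        labels = list(self.leaf_label.values())
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")
        for s in self.supports.values():
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError(f"support {s} outside [0, 1] after normalization")

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        """Parse a single Newick tree, normalizing support dialects.

        Internal-node labels are read as supports.  If any parsed support
        exceeds 1, the tree is taken to use the percentage dialect and all
        supports are divided by 100.  Unlabelled internal edges carry an
        absent (``None``) support.  Supports outside [0, 100] are an error.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise NewickParseError(f"unparseable Newick: {exc}") from exc

        adjacency: dict[int, set[int]] = {}
        leaf_label: dict[int, str] = {}
        raw_supports: dict[Edge, Optional[float]] = {}
        lengths: dict[Edge, float] = {}
        node_id: dict = {}

        for i, node in enumerate(dtree.preorder_node_iter()):
            node_id[node] = i
            adjacency[i] = set()
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickParseError("leaf without a label")
                leaf_label[i] = node.taxon.label

        for node in dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            u, v = node_id[node.parent_node], node_id[node]
            adjacency[u].add(v)
            adjacency[v].add(u)
            edge = frozenset((u, v))
            if node.edge.length is not None:
                if node.edge.length < 0:
                    raise NewickParseError("negative branch length")
                lengths[edge] = float(node.edge.length)
            if v not in leaf_label:  # internal edge: child-side label is support
                if node.label is None or node.label == "":
                    raw_supports[edge] = None
                else:
                    try:
                        s = float(node.label)
                    except ValueError as exc:
                        raise NewickParseError(
                            f"internal label {node.label!r} is not a support value"
                        ) from exc
                    if not 0.0 <= s <= 100.0:
                        raise NewickParseError(f"support {s} outside [0, 100]")
                    raw_supports[edge] = s

        supports = normalize_supports(raw_supports)
        root = node_id[dtree.seed_node]
        if len(adjacency) == 1:
            raise NewickParseError("tree has a single node")
        return cls(adjacency, leaf_label, supports, lengths, root=root)

    # ------------------------------------------------------------------ #
    # basic queries

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def leaves(self) -> set[str]:
        return set(self.leaf_label.values())

    def leaf_nodes(self) -> list[int]:
        return sorted(self.leaf_label)

    def node_of_leaf(self, label: str) -> int:
        for n, lab in self.leaf_label.items():
            if lab == label:
                return n
        raise KeyError(label)

    def is_leaf(self, node: int) -> bool:
        return node in self.leaf_label

    def edges(self) -> Iterator[tuple[int, int]]:
        seen = set()
        for u, vs in self.adjacency.items():
            for v in vs:
                e = frozenset((u, v))
                if e not in seen:
                    seen.add(e)
                    yield (u, v)

    def internal_edges(self) -> Iterator[tuple[int, int]]:
        for u, v in self.edges():
            if u not in self.leaf_label and v not in self.leaf_label:
                yield (u, v)

    def side_nodes(self, u: int, v: int) -> set[int]:
        """Nodes reachable from ``v`` without crossing the edge (u, v)."""
        seen = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y in self.adjacency[x]:
                if y != u and y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    def side_labels(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the ``v`` side of the edge (u, v)."""
        return frozenset(
            self.leaf_label[n] for n in self.side_nodes(u, v) if n in self.leaf_label
        )

    # ------------------------------------------------------------------ #
    # transformations

    def copy(self) -> "GeneTree":
        return GeneTree(self.adjacency, self.leaf_label, self.supports,
                        self.lengths, root=self.root)

    def collapse(self, threshold: float) -> "GeneTree":
        """Contract internal edges supported below ``threshold``.

        Edges with absent support are treated as below threshold and
        contracted too.  Leaves and well-supported edges are untouched;
        contraction creates polytomies.
        """
        to_contract = {
            e for e, s in self.supports.items() if s is None or s < threshold
        }
        parent = {u: u for u in self.adjacency}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in to_contract:
            u, v = tuple(e)
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[rv] = ru

        adjacency: dict[int, set[int]] = {}
        supports: dict[Edge, Optional[float]] = {}
        lengths: dict[Edge, float] = {}
        for u, vs in self.adjacency.items():
            ru = find(u)
            adjacency.setdefault(ru, set())
            for v in vs:
                rv = find(v)
                if ru != rv:
                    adjacency[ru].add(rv)
                    adjacency.setdefault(rv, set()).add(ru)
        for e, s in self.supports.items():
            u, v = tuple(e)
            ru, rv = find(u), find(v)
            if ru != rv:
                supports[frozenset((ru, rv))] = s
        for e, l in self.lengths.items():
            u, v = tuple(e)
            ru, rv = find(u), find(v)
            if ru != rv:
                lengths[frozenset((ru, rv))] = l
        leaf_label = {find(n): lab for n, lab in self.leaf_label.items()}
        return GeneTree(adjacency, leaf_label, supports, lengths, root=find(self.root))

    def restrict(self, keep_labels: Iterable[str]) -> "GeneTree":
        """Induced tree on a subset of leaves.

        Leaves outside ``keep_labels`` are pruned; internal nodes left with
        degree 1 are removed and degree-2 internal nodes are suppressed.
        When two edges are merged by suppression the merged edge carries
        the minimum of the present supports (conservative) and the sum of
        the present branch lengths.
        """
        keep = set(keep_labels)
        unknown = keep - self.leaves()
        if unknown:
            raise KeyError(f"labels not in tree: {sorted(unknown)}")
        adjacency = {u: set(vs) for u, vs in self.adjacency.items()}
        leaf_label = dict(self.leaf_label)
        supports = dict(self.supports)
        lengths = dict(self.lengths)

        def drop_node(n: int) -> None:
            for m in adjacency.pop(n, set()):
                adjacency[m].discard(n)
                e = frozenset((n, m))
                supports.pop(e, None)
                lengths.pop(e, None)

        for n, lab in list(leaf_label.items()):
            if lab not in keep:
                drop_node(n)
                del leaf_label[n]

        changed = True
        while changed:
            changed = False
            for n in list(adjacency):
                if n in leaf_label:
                    continue
                deg = len(adjacency[n])
                if deg <= 1:
                    drop_node(n)
                    changed = True
                elif deg == 2:
                    a, b = tuple(adjacency[n])
                    ea, eb = frozenset((n, a)), frozenset((n, b))
                    merged = frozenset((a, b))
                    if b in adjacency[a]:
                        # suppression would create a parallel edge; drop the node
                        drop_node(n)
                        changed = True
                        continue
                    present = [s for s in (supports.get(ea), supports.get(eb)) if s is not None]
                    is_internal = a not in leaf_label and b not in leaf_label
                    drop_len = [l for l in (lengths.get(ea), lengths.get(eb)) if l is not None]
                    drop_node(n)
                    adjacency[a].add(b)
                    adjacency[b].add(a)
                    if is_internal:
                        supports[merged] = min(present) if present else None
                    if drop_len:
                        lengths[merged] = sum(drop_len)
                    changed = True
        root = self.root if self.root in adjacency else None
        if not adjacency:
            raise ValueError("restriction removed every node")
        return GeneTree(adjacency, leaf_label, supports, lengths, root=root)

    # ------------------------------------------------------------------ #
    # serialization

    def to_newick(self) -> str:
        """Serialize with supports as internal-node labels.

        Absent supports produce unlabelled internal nodes; branch lengths
        are written only where present.
        """
        root = self.root
        if root in self.leaf_label and len(self.adjacency) > 1:
            root = next(iter(self.adjacency[root]))

        def fmt_node(node: int, parent: Optional[int]) -> str:
            children = [c for c in sorted(self.adjacency[node]) if c != parent]
            if not children:  # leaf
                s = self.leaf_label[node]
            else:
                inner = ",".join(fmt_node(c, node) for c in children)
                s = f"({inner})"
                if parent is not None:
                    sup = self.supports.get(frozenset((node, parent)))
                    if sup is not None:
                        s += repr(sup)  # shortest exact float representation
            if parent is not None:
                e = frozenset((node, parent))
                if e in self.lengths:
                    s += f":{self.lengths[e]!r}"
            return s

        return fmt_node(root, None) + ";"

    # ------------------------------------------------------------------ #

    def __eq__(self, other: object) -> bool:
        """Equality as unrooted support-labelled trees (split-based)."""
        if not isinstance(other, GeneTree):
            return NotImplemented
        if self.leaves() != other.leaves():
            return False
        return self._split_supports() == other._split_supports()

    def _split_supports(self) -> dict[frozenset, Optional[float]]:
        all_leaves = frozenset(self.leaves())
        out: dict[frozenset, Optional[float]] = {}
        for u, v in self.internal_edges():
            side = self.side_labels(u, v)
            key = min(side, all_leaves - side, key=sorted)
            out[key] = self.supports[frozenset((u, v))]
        return out


def normalize_supports(
    raw: dict[Edge, Optional[float]]
) -> dict[Edge, Optional[float]]:
    """Rescale a 0-100 support dialect to [0, 1]; idempotent.

    If any present support exceeds 1, every present support is divided
    by 100.  Applying the rule twice equals applying it once because the
    rescaled values are all at most 1.
    """
    present = [s for s in raw.values() if s is not None]
    if present and max(present) > 1.0:
        return {e: (None if s is None else s / 100.0) for e, s in raw.items()}
    return dict(raw)
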