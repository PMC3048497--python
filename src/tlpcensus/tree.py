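"""Minimal phylogenetic tree container shared by the phylogeny and I/O modules.

Trees are stored rooted-at-a-basal-multifurcation (the usual representation
of an unrooted tree); all split-based operations (bipartitions, Robinson-
Foulds) are rooting-invariant.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional


class TreeNode:
    """A node of a phylogenetic tree.

    Parameters
    ----------
    name : leaf label (internal nodes usually unnamed).
    length : branch length to the parent (ignored on the root).
    support : bootstrap support of the edge to the parent, in [0, 1].
    """

    __slots__ = ("name", "length", "support", "children")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
        children: Optional[list["TreeNode"]] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = children if children is not None else []

    # -- traversal -------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]

    def n_edges(self) -> int:
        return sum(1 for n in self.walk()) - 1

    # -- splits ----------------------------------------------------------

    def _leafsets(self) -> dict[int, frozenset]:
        out: dict[int, frozenset] = {}

        def rec(node: TreeNode) -> frozenset:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(rec(c) for c in node.children))
            out[id(node)] = s
            return s

        rec(self)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted tree.

        Each split is represented by the side that does *not* contain the
        lexicographically smallest leaf, so representations are comparable
        across rootings.
        """
        leafsets = self._leafsets()
        all_leaves = leafsets[id(self)]
        if len(all_leaves) < 4:
            return set()
        ref = min(all_leaves)
        splits = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = leafsets[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def edge_lengths(self) -> dict[frozenset, float]:
        """Map each edge's split (including trivial leaf splits) to its length.

        Edges incident to the root multifurcation that lead to complementary
        leaf sets are the same unrooted edge; a rooted-on-an-edge tree (root
        with two children) contributes the two root branch lengths to one
        unrooted edge, and they are summed.
        """
        leafsets = self._leafsets()
        all_leaves = leafsets[id(self)]
        ref = min(all_leaves)
        out: dict[frozenset, float] = {}

        def rec(node: TreeNode) -> None:
            for child in node.children:
                side = leafsets[id(child)]
                if ref in side:
                    side = all_leaves - side
                out[side] = out.get(side, 0.0) + child.length
                rec(child)

        rec(self)
        return out

    # -- distances -------------------------------------------------------

    def distance_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """Additive leaf-to-leaf path-length matrix (labels sorted)."""
        labels = sorted(self.leaf_names())
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        mat = [[0.0] * n for _ in range(n)]

        def rec2(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            parts = []
            for child in node.children:
                part = rec2(child)
                parts.append({leaf: dist + child.length for leaf, dist in part.items()})
            for a in range(len(parts)):
                for b in range(a + 1, len(parts)):
                    for la, da in parts[a].items():
                        for lb, db in parts[b].items():
                            i, j = index[la], index[lb]
                            mat[i][j] = mat[j][i] = da + db
            merged: dict[str, float] = {}
            for part in parts:
                merged.update(part)
            return merged

        rec2(self)
        return labels, mat

    # -- newick ----------------------------------------------------------

    def format_newick(self, precision: int = 6, support_percent: bool = True) -> str:
        """Newick string; bootstrap supports become integer percent labels."""

        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if node.support is not None and support_percent:
                    body += str(int(node.support * 100 + 0.5))
                elif node.name:
                    body += node.name
            if top:
                return body
            return body + f":{node.length:.{precision}f}"

        return fmt(self, True) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "TreeNode":
        """Parse a Newick string (via dendropy); integer internal-node labels
        are interpreted as bootstrap percentages."""
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

        def convert(dnode) -> TreeNode:
            node = cls()
            if dnode.taxon is not None:
                node.name = dnode.taxon.label
            node.length = dnode.edge.length if dnode.edge.length is not None else 0.0
            label = dnode.label
            if label is not None and dnode.child_nodes():
                try:
                    node.support = float(label) / 100.0
                except ValueError:
                    node.name = label
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return convert(dtree.seed_node)


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between two trees on
    the same leaf set."""
    la, lb = set(a.leaf_names()), set(b.leaf_names())
    if la != lb:
        raise ValueError("trees have different leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())
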