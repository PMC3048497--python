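"""Distance phylogeny: p-distance with pairwise deletion, Poisson correction,
Neighbour-Joining, bootstrap support, and anchor-based clade assignment.

The estimator chain is the classic amino-acid one: per sequence pair, only
alignment columns where *both* rows carry a scoreable residue are used
(pairwise deletion; gaps and X are missing data), the proportion of
differing usable sites p is corrected for multiple hits as d = -ln(1 - p),
and the Saitou-Nei Neighbour-Joining algorithm agglomerates the corrected
matrix.  Bootstrap support of an internal edge is the fraction of
column-resampled replicates whose NJ tree contains the same bipartition.

Determinism: Q-criterion ties are broken on the lexicographically smallest
pair of cluster representatives (the minimum leaf label of each cluster),
and the bootstrap is driven by a single seeded generator, so identical
inputs and seed reproduce trees and supports bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tlpcensus.io_formats import GAP, Alignment
from tlpcensus.tree import TreeNode, robinson_foulds

__all__ = [
    "DistanceMatrix",
    "CladeAssignment",
    "pdistance_matrix",
    "poisson_correct",
    "nj_tree",
    "bootstrap_support",
    "assign_clades",
    "robinson_foulds",
]

_MISSING = (GAP, "X")


@dataclass
class DistanceMatrix:
    """Poisson-corrected distances with their p and usable-site companions.

    ``undefined[i, j]`` is True when a pair had zero usable columns or
    p >= 1 (the Poisson correction diverges); such matrices are rejected by
    tree building.
    """

    labels: tuple[str, ...]
    p: np.ndarray
    d: np.ndarray
    usable: np.ndarray
    undefined: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.undefined[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out


def _encode(alignment: Alignment) -> np.ndarray:
    """Rows as small-int codes; gaps and X become -1 (missing)."""
    arr = np.frombuffer(
        "".join(alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(alignment.n_rows, alignment.n_columns).astype(np.int16)
    for ch in _MISSING:
        arr[arr == ord(ch)] = -1
    return arr


def poisson_correct(p):
    """Multiple-hit correction d = -ln(1 - p); p >= 1 yields NaN (undefined)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(p < 1.0, -np.log1p(-np.clip(p, None, 1.0 - 1e-300)), np.nan)
    if d.ndim == 0:
        return float(d)
    return d


def pdistance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise p-distances under pairwise deletion, plus their Poisson
    correction."""
    if alignment.n_rows < 2:
        raise ValueError("need at least two sequences")
    arr = _encode(alignment)
    valid = arr >= 0
    n = alignment.n_rows
    p = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    undefined = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            u = int(mask.sum())
            usable[i, j] = usable[j, i] = u
            if u == 0:
                undefined[i, j] = undefined[j, i] = True
                p[i, j] = p[j, i] = np.nan
                continue
            pij = float(((arr[i] != arr[j]) & mask).sum()) / u
            p[i, j] = p[j, i] = pij
            if pij >= 1.0:
                undefined[i, j] = undefined[j, i] = True
    d = poisson_correct(p)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(p, 0.0)
    return DistanceMatrix(tuple(alignment.ids), p, d, usable, undefined)


def _nj_from_matrix(labels: tuple[str, ...], dist: np.ndarray) -> TreeNode:
    """Saitou-Nei agglomeration with deterministic tie-breaking."""
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour-joining needs at least 3 taxa")
    if np.allclose(dist, 0.0):
        # all sequences equidistant at zero: nothing is resolvable
        return TreeNode(children=[TreeNode(name=lab, length=0.0) for lab in labels])

    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dist
    nodes: dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    reps: dict[int, str] = {i: labels[i] for i in range(n)}
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        # clamp negative estimates to zero, moving the deficit to the sibling
        if li < 0.0:
            lj = D[i, j]
            li = 0.0
        elif lj < 0.0:
            li = D[i, j]
            lj = 0.0
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length, child_j.length = li, lj
        u = nxt
        nxt += 1
        nodes[u] = TreeNode(children=[child_i, child_j])
        reps[u] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda k: reps[k])
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, l in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(0.0, l)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-Joining tree from a fully defined distance matrix.

    Raises when any pair is undefined (zero usable sites or p >= 1),
    naming the offending pairs.
    """
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")
    return _nj_from_matrix(dm.labels, dm.d)


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 1000,
    seed: int | None = None,
) -> tuple[TreeNode, dict]:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (one seeded
    generator drives all replicates), rebuilds p-distance -> Poisson -> NJ,
    and contributes its bipartitions.  Support of an internal edge is the
    fraction of *all* replicates containing its split: replicates whose
    resampled matrix has undefined pairs cannot support any split and are
    tallied in the diagnostics instead of being silently discarded.
    """
    dm = pdistance_matrix(alignment)
    main = nj_tree(dm)
    n_cols = alignment.n_columns
    arr = _encode(alignment)
    valid = arr >= 0
    n = alignment.n_rows
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pair_valid = np.stack([valid[i] & valid[j] for i, j in pairs])
    pair_diff = np.stack(
        [((arr[i] != arr[j]) & pair_valid[k]) for k, (i, j) in enumerate(pairs)]
    )

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n_undef = 0
    labels = tuple(alignment.ids)
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, n_cols)
        u = pair_valid[:, idx].sum(axis=1)
        if np.any(u == 0):
            n_undef += 1
            continue
        k = pair_diff[:, idx].sum(axis=1)
        p = k / u
        if np.any(p >= 1.0):
            n_undef += 1
            continue
        d = -np.log1p(-p)
        dist = np.zeros((n, n))
        for idx_pair, (i, j) in enumerate(pairs):
            dist[i, j] = dist[j, i] = d[idx_pair]
        rep_tree = _nj_from_matrix(labels, dist)
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    leafsets = main._leafsets()
    all_leaves = leafsets[id(main)]
    ref = min(all_leaves)
    for node in main.walk():
        if node is main or node.is_leaf:
            continue
        side = leafsets[id(node)]
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            node.support = counts.get(side, 0) / n_reps
    diagnostics = {
        "n_replicates": n_reps,
        "n_undefined_replicates": n_undef,
        "seed": seed,
    }
    return main, diagnostics


@dataclass
class CladeAssignment:
    """Leaf -> clade mapping produced from anchor leaf sets."""

    assignment: dict[str, str]
    anchors: dict[str, set[str]]

    def members(self, clade: str) -> set[str]:
        return {leaf for leaf, c in self.assignment.items() if c == clade}


def assign_clades(tree: TreeNode, anchors: dict[str, set[str] | list[str]]) -> CladeAssignment:
    """Expand anchor leaf sets into clades on the tree.

    Each clade is the minimal subtree spanning its anchors together with the
    leaves hanging directly off that subtree's internal nodes.  Leaves
    claimed by more than one clade, or by none, are labelled ``unplaced``.
    Anchor sets must be disjoint and all anchors present in the tree.
    """
    anchors = {c: set(s) for c, s in anchors.items()}
    leaf_nodes: dict[str, TreeNode] = {}
    parent: dict[int, TreeNode] = {}
    for node in tree.walk():
        if node.is_leaf:
            leaf_nodes[node.name] = node
        for child in node.children:
            parent[id(child)] = node
    all_leaves = set(leaf_nodes)
    seen: set[str] = set()
    for clade, members in anchors.items():
        missing = members - all_leaves
        if missing:
            raise ValueError(f"anchor leaves not in tree: {sorted(missing)}")
        overlap = members & seen
        if overlap:
            raise ValueError(f"anchor sets overlap: {sorted(overlap)}")
        seen |= members

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        out = [node]
        while id(node) in parent:
            node = parent[id(node)]
            out.append(node)
        return out

    claims: dict[str, list[str]] = {leaf: [] for leaf in all_leaves}
    for clade, members in anchors.items():
        anchor_nodes = [leaf_nodes[m] for m in sorted(members)]
        # spanning subtree = union of node paths between anchors
        base = path_to_root(anchor_nodes[0])
        base_ids = [id(x) for x in base]
        span: set[int] = {id(anchor_nodes[0])}
        node_by_id = {id(anchor_nodes[0]): anchor_nodes[0]}
        for other in anchor_nodes[1:]:
            path = path_to_root(other)
            path_ids = {id(x): k for k, x in enumerate(path)}
            # walk up from the first anchor until the common ancestor
            for x in base:
                if id(x) in path_ids:
                    lca = x
                    break
                span.add(id(x))
                node_by_id[id(x)] = x
            span.add(id(lca))
            node_by_id[id(lca)] = lca
            for x in path:
                if x is lca:
                    break
                span.add(id(x))
                node_by_id[id(x)] = x
        expansion = set(members)
        for leaf, node in leaf_nodes.items():
            p = parent.get(id(node))
            if p is not None and id(p) in span and not node_by_id[id(p)].is_leaf:
                expansion.add(leaf)
        for leaf in expansion:
            claims[leaf].append(clade)

    assignment = {
        leaf: cs[0] if len(cs) == 1 else "unplaced" for leaf, cs in claims.items()
    }
    for leaf, cs in claims.items():
        if not cs:
            assignment[leaf] = "unplaced"
    return CladeAssignment(assignment=assignment, anchors=anchors)
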