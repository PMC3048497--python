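"""Independent oracles used by the test suite.

Everything here is deliberately naive (per-base booleans, sliding windows,
exhaustive enumeration, dense pH grids) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

STD = set("ACDEFGHIKLMNPQRSTVWY")


# -- boundary motifs --------------------------------------------------------


def brute_force_motif_hits(seq: str) -> list[tuple[str, int]]:
    """Character-by-character sliding-window matcher for the two boundary
    motifs; returns (kind, start) tuples."""
    hits = []
    for i in range(len(seq) - 7):
        w = seq[i : i + 8]
        if (
            w[0] == "N"
            and w[1] in STD
            and w[2] == "C"
            and w[3] in STD
            and w[4] in STD
            and w[5] in STD
            and w[6] in "VI"
            and w[7] == "W"
        ):
            hits.append(("N-terminal", i))
    for i in range(len(seq) - 6):
        w = seq[i : i + 7]
        if (
            w[0] == "Y"
            and w[1] in STD
            and w[2] in "IV"
            and w[3] in STD
            and w[4] == "F"
            and w[5] == "C"
            and w[6] in STD
        ):
            hits.append(("C-terminal", i))
    return sorted(hits, key=lambda h: (h[1], h[0]))


# -- isoelectric point ------------------------------------------------------

_PH_STEP = 1e-5
_PH_GRID = None
_CURVES = None


def _titration_curves():
    """Cache the per-group charge curves on a dense pH grid (step 1e-5)."""
    global _PH_GRID, _CURVES
    if _CURVES is None:
        ph = np.arange(0.0, 14.0 + _PH_STEP, _PH_STEP)
        pka = {
            "nterm": 8.6, "cterm": 3.6,
            "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,
            "H": 6.5, "K": 10.8, "R": 12.5,
        }
        curves = {
            "nterm": 1.0 / (1.0 + 10.0 ** (ph - pka["nterm"])),
            "cterm": -1.0 / (1.0 + 10.0 ** (pka["cterm"] - ph)),
        }
        for aa in "HKR":
            curves[aa] = 1.0 / (1.0 + 10.0 ** (ph - pka[aa]))
        for aa in "DECY":
            curves[aa] = -1.0 / (1.0 + 10.0 ** (pka[aa] - ph))
        _PH_GRID, _CURVES = ph, curves
    return _PH_GRID, _CURVES


def grid_search_pi(sequence: str) -> float:
    """pH grid search (resolution 1e-5) minimizing |net charge|."""
    ph, curves = _titration_curves()
    charge = curves["nterm"] + curves["cterm"]
    for aa in "HKRDECY":
        n = sequence.count(aa)
        if n:
            charge = charge + n * curves[aa]
    return float(ph[np.argmin(np.abs(charge))])


# -- interval union ---------------------------------------------------------


def per_base_union_length(intervals, domain=10_000) -> int:
    covered = np.zeros(domain, dtype=bool)
    for start, end in intervals:
        covered[start:end] = True
    return int(covered.sum())


# -- exhaustive least-squares tree search -----------------------------------


def _all_topologies(labels):
    """All unrooted binary topologies, each as a nested-tuple tree rooted at
    a trifurcation."""

    def insert_everywhere(tree, leaf):
        # tree is either a label (leaf) or a tuple of subtrees
        results = []
        if isinstance(tree, tuple):
            for k, sub in enumerate(tree):
                for new_sub in insert_everywhere(sub, leaf):
                    results.append(tuple(new_sub if m == k else tree[m] for m in range(len(tree))))
        results.append((tree, leaf))
        return results

    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        nxt = []
        for t in trees:
            # insert into each of the three root subtrees' edges, or next to them
            for k in range(3):
                for new_sub in insert_everywhere(t[k], leaf):
                    nxt.append(tuple(new_sub if m == k else t[m] for m in range(3)))
        trees = nxt
    return trees


def _edges_and_paths(tree, labels):
    """Edge list and per-leaf-pair edge-incidence rows for a nested tree."""
    edges = []
    leaf_path: dict[str, list[int]] = {}

    def rec(node, path):
        if isinstance(node, tuple):
            for sub in node:
                eid = len(edges)
                edges.append(eid)
                rec(sub, path + [eid])
        else:
            leaf_path[node] = path

    rec(tree, [])
    n_edges = len(edges)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        pa, pb = set(leaf_path[a]), set(leaf_path[b])
        row = np.zeros(n_edges)
        for e in pa ^ pb:
            row[e] = 1.0
        rows.append(row)
    return np.array(rows)


def _splits(tree, all_labels):
    """Non-trivial splits of a nested-tuple tree, normalized like the
    package's bipartitions (side without the smallest label)."""
    ref = min(all_labels)
    out = set()

    def leaves(node):
        if isinstance(node, tuple):
            s = frozenset()
            for sub in node:
                s |= leaves(sub)
            return s
        return frozenset([node])

    def rec(node):
        if not isinstance(node, tuple):
            return
        for sub in node:
            side = leaves(sub)
            if ref in side:
                side = frozenset(all_labels) - side
            if 2 <= len(side) <= len(all_labels) - 2:
                out.add(side)
            rec(sub)

    rec(tree)
    return out


def least_squares_best_topology(labels, dist):
    """Exhaustive OLS branch-length fit over all unrooted topologies; returns
    the split set of the topology with the smallest residual sum of squares."""
    labels = list(labels)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    y = np.array([dist[i][j] for i, j in pairs])
    best = None
    best_ssq = None
    for topo in _all_topologies(labels):
        X = _edges_and_paths(topo, labels)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssq = float(((X @ beta - y) ** 2).sum())
        if best_ssq is None or ssq < best_ssq - 1e-12:
            best_ssq = ssq
            best = topo
    return _splits(best, labels)
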