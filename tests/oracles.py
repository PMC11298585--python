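"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: alignment scores come
from exhaustive enumeration of all gapped alignments, tree distances from
path lengths on explicitly built trees, and sphere areas from closed-form
spherical-cap geometry.
"""

from __future__ import annotations

import collections
import math

import numpy as np

from lactamscan.pairwise_align import load_matrix
from lactamscan.phylo import DistMatrix, TreeNode

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_global_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                           gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap score by enumerating every alignment path.

    Gap convention: a gap of length L costs gap_open + L * gap_extend.
    Exponential time; only usable for short sequences.
    """
    m = load_matrix(matrix_name)
    best = -math.inf

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + m[a[i], b[j]], "D")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "I"
                                   else gap_open + gap_extend), "I")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "J"
                                   else gap_open + gap_extend), "J")

    rec(0, 0, 0.0, None)
    return best


def enumerate_local_score(a: str, b: str, **kw) -> float:
    """Optimal local score: best global score over all substring pairs."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, enumerate_global_score(a[i0:i1], b[j0:j1], **kw))
    return best


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(20, size=length))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_taxa: int,
                         min_len: float = 0.05, max_len: float = 1.0) -> TreeNode:
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(label=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        new = TreeNode(children=[(nodes[i], rng.uniform(min_len, max_len)),
                                 (nodes[j], rng.uniform(min_len, max_len))])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [new]
    return TreeNode(children=[(node, rng.uniform(min_len, max_len))
                              for node in nodes])


def tree_distance_matrix(tree: TreeNode) -> DistMatrix:
    """Leaf-to-leaf path-length distances of an explicit tree."""
    adj = collections.defaultdict(list)
    leaves: dict[str, int] = {}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            leaves[node.label] = id(node)
        for child, length in node.children:
            adj[id(node)].append((id(child), length))
            adj[id(child)].append((id(node), length))
            walk(child)

    walk(tree)
    labels = sorted(leaves)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = {leaves[a]: 0.0}
        stack = [leaves[a]]
        while stack:
            u = stack.pop()
            for v, length in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + length
                    stack.append(v)
        for j, b in enumerate(labels):
            d[i, j] = dist[leaves[b]]
    d = (d + d.T) / 2.0  # remove float asymmetry from per-leaf traversals
    return DistMatrix(tuple(labels), d)


def quartet_least_squares_topology(dm: DistMatrix) -> frozenset:
    """Best 4-taxon topology by ordinary least squares on the 6 distances.

    Returns the cherry {a, b} of the winning quartet ab|cd as a frozenset of
    two labels.
    """
    if len(dm.labels) != 4:
        raise ValueError("quartet oracle needs exactly 4 taxa")
    idx = range(4)
    pairs = [(i, j) for i in idx for j in idx if i < j]
    d = np.array([dm.matrix[i, j] for i, j in pairs])
    best = (math.inf, None)
    # topologies: cherry (0,k) for k in 1..3
    for k in (1, 2, 3):
        others = [x for x in (1, 2, 3) if x != k]
        # parameters: 4 pendant edges + 1 internal edge
        rows = []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] = 1.0
            row[j] = 1.0
            same_side = ({i, j} == {0, k}) or ({i, j} == set(others))
            if not same_side:
                row[4] = 1.0
            rows.append(row)
        a = np.array(rows)
        sol, *_ = np.linalg.lstsq(a, d, rcond=None)
        sse = float(np.sum((a @ sol - d) ** 2))
        if sse < best[0] - 1e-12:
            best = (sse, frozenset({dm.labels[0], dm.labels[k]}))
    return best[1]


def nj_cherry_with_zero(tree: TreeNode) -> set[frozenset]:
    """All cherries (leaf pairs joined by one internal node) of a tree."""
    out = set()

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        leaf_children = [c.label for c, _ in node.children if c.is_leaf]
        if len(node.children) == 2 and len(leaf_children) == 2:
            out.add(frozenset(leaf_children))
        for child, _ in node.children:
            walk(child)

    walk(tree)
    return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def two_sphere_sasa(r: float, d: float, probe: float) -> float:
    """Closed-form SASA of one of two equal spheres at center distance d."""
    rp = r + probe
    if d >= 2 * rp:
        return 4.0 * math.pi * rp * rp
    h = rp - d / 2.0              # height of the buried spherical cap
    return 4.0 * math.pi * rp * rp - 2.0 * math.pi * rp * h
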