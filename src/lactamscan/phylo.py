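"""Distance-based neighbor-joining phylogeny of TE-domain sequences.

Distances are ``1 - fractional identity`` from global pairwise alignment
(optionally Poisson-corrected). Trees are built with the Saitou-Nei
neighbor-joining algorithm and written as Newick. On additive distance
matrices NJ recovers the generating topology and branch lengths exactly,
which is the main correctness property the test suite exercises.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .pairwise_align import AlignmentParams, align
from .seqio import ProteinRecord


@dataclass(frozen=True)
class DistMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if np.any(m < 0) or np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class TreeNode:
    """Tree node; ``children`` holds (child, branch length) pairs."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def distance_matrix(records: list[ProteinRecord],
                    params: AlignmentParams | None = None,
                    corrected: bool = False) -> DistMatrix:
    """Pairwise 1-identity distances over global alignments.

    ``corrected=True`` applies the Poisson correction ``-ln(1 - d)``
    (saturated pairs are capped just below full saturation).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 sequences")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    params = params or AlignmentParams(mode="global")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align(records[i].sequence, records[j].sequence, params)
            dist = 1.0 - aln.identity
            if corrected:
                dist = -math.log(max(1.0 - dist, 1e-6))
            d[i, j] = d[j, i] = dist
    return DistMatrix(labels=tuple(labels), matrix=d)


def nj_tree(dm: DistMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Joins the pair minimizing the Q-criterion at each step (ties broken by
    the smaller index pair, i.e. first by i then by j in the current taxon
    ordering, which itself follows input order). Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch. The
    returned root is the standard unrooted trifurcation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lbl) for lbl in dm.labels]

    def clamp(pair: list[tuple[TreeNode, float]]) -> list[tuple[TreeNode, float]]:
        (na, la), (nb, lb) = pair
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return [(na, max(la, 0.0)), (nb, max(lb, 0.0))]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j)
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode(children=clamp([(nodes[i], li), (nodes[j], lj)]))
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new

    # final trifurcation, closed-form branch lengths
    d12, d13, d23 = d[0, 1], d[0, 2], d[1, 2]
    l1 = 0.5 * (d12 + d13 - d23)
    l2 = 0.5 * (d12 + d23 - d13)
    l3 = 0.5 * (d13 + d23 - d12)
    children = [(nodes[0], l1), (nodes[1], l2), (nodes[2], l3)]
    fixed = []
    for node, length in children:
        fixed.append((node, max(length, 0.0)))
    return TreeNode(children=fixed)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_PLAIN_LABEL = re.compile(r"^[^\s()\[\]{}:;,\"']+$")


def _fmt_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths (lossless), semicolon-terminated."""

    def fmt(length: float) -> str:
        length = float(length)
        if length == int(length):
            return str(int(length))
        return repr(length)

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            return _fmt_label(node.label)
        inner = ",".join(f"{rec(child)}:{fmt(length)}"
                         for child, length in node.children)
        label = _fmt_label(node.label) if node.label else ""
        return f"({inner}){label}"

    return rec(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse the Newick subset produced by :func:`write_newick`."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise ValueError("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_node() -> TreeNode:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = []
            while True:
                child = parse_node()
                length = 0.0
                if pos < len(s) and s[pos] == ":":
                    pos += 1
                    start = pos
                    while pos < len(s) and s[pos] not in "(),:;":
                        pos += 1
                    length = float(s[start:pos])
                children.append((child, length))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = parse_label()
            return TreeNode(label=label or None, children=children)
        label = parse_label()
        if not label:
            raise ValueError(f"empty leaf label at position {pos}")
        return TreeNode(label=label)

    node = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters after position {pos}")
    return node


# ---------------------------------------------------------------------------
# comparison helpers
# ---------------------------------------------------------------------------

def canonical(tree: TreeNode, decimals: int = 9) -> str:
    """Order-independent canonical form (for isomorphism comparison)."""

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        parts = sorted(f"{rec(child)}:{round(length, decimals):.{decimals}g}"
                       for child, length in node.children)
        return "(" + ",".join(parts) + ")"

    return rec(tree)


def splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (one side each) induced by internal edges."""
    all_leaves = frozenset(tree.leaves())
    out: set[frozenset[str]] = set()

    def rec(node: TreeNode):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            part = rec(child)
            if 1 < len(part) < len(all_leaves) - 1:
                out.add(min(part, all_leaves - part, key=sorted))
            below |= part
        return below

    rec(tree)
    return out


def is_monophyletic(tree: TreeNode, group: set[str]) -> bool:
    """True when ``group`` forms one side of some edge of the unrooted tree."""
    all_leaves = set(tree.leaves())
    if not group <= all_leaves:
        raise ValueError("group contains unknown taxa")
    if len(group) <= 1 or group == all_leaves:
        return True
    target = min(frozenset(group), frozenset(all_leaves - group), key=sorted)
    if len(group) == len(all_leaves) - 1 or len(group) == 1:
        return True
    return target in splits(tree)
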