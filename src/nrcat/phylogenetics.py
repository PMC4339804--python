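"""Distance-based phylogenetics.

p-distances from a multiple alignment, Poisson multiple-hit correction
``d = -ln(1 - p)``, Saitou–Nei neighbor joining with a deterministic
tie-break, column-bootstrap bipartition support, and Newick round-tripping.

Trees are :class:`skbio.TreeNode` objects (unrooted trees carry a
trifurcating root). Bootstrap supports are stored both as the float
attribute ``support`` and as the internal node ``name`` so that plain
Newick serialisation keeps them, as MEGA-style NJ output does.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skbio import TreeNode

from .seqcore import GAP, MSA

logger = logging.getLogger("nrcat")

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "poisson_distance",
    "poisson_correct",
    "nj_tree",
    "bootstrap_support",
    "tree_splits",
    "same_topology",
    "write_newick",
    "read_newick",
    "msa_nj_builder",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate taxa ids")
        object.__setattr__(self, "matrix", m)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.matrix[i, j])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance(msa: MSA, deletion_mode: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing residues per pair of rows.

    ``pairwise`` deletion compares columns where both rows are non-gap;
    ``complete`` first drops every column with a gap in any row.
    """
    if len(msa.ids) < 2:
        raise ValueError("p_distance requires >= 2 rows")
    if deletion_mode not in ("pairwise", "complete"):
        raise ValueError("deletion_mode must be 'pairwise' or 'complete'")
    rows = np.array([list(r) for r in msa.rows])
    nongap = rows != GAP
    if deletion_mode == "complete":
        keep = nongap.all(axis=0)
        rows = rows[:, keep]
        nongap = nongap[:, keep]
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(
                    f"no comparable sites between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            diff = int((rows[i, both] != rows[j, both]).sum())
            d[i, j] = d[j, i] = diff / comp
    return DistanceMatrix(tuple(msa.ids), d)


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance ``d = -ln(1 - p)`` for ``0 <= p < 1``."""
    if not (0.0 <= p < 1.0):
        raise ValueError(f"p-distance {p} is saturated or out of range [0, 1)")
    return -math.log1p(-p)


def poisson_correct(dm: DistanceMatrix) -> DistanceMatrix:
    """Apply the Poisson correction elementwise to a p-distance matrix."""
    n = len(dm.ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = poisson_distance(dm.matrix[i, j])
    return DistanceMatrix(dm.ids, out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def _subtree_min_leaf(node: TreeNode) -> str:
    return node.name if node.is_tip() else min(t.name for t in node.tips())


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Q-criterion agglomeration with a deterministic tie-break: among pairs
    with equal Q, the pair whose (sorted) smallest-leaf labels compare
    lowest is joined first. Negative branch-length estimates are clamped to
    zero and the clamped deficit logged. The returned tree is unrooted,
    represented with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("nj_tree requires >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    keys: list[str] = list(dm.ids)  # tie-break key: smallest leaf label in subtree
    D = dm.matrix.copy()

    def clamp(val: float, where: str) -> float:
        if val < 0:
            logger.debug("NJ: clamped negative branch length %.6g at %s", val, where)
            return 0.0
        return val

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        best: tuple[float, str, str] | None = None
        bi = bj = -1
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - rowsum[i] - rowsum[j]
                lo, hi = sorted((keys[i], keys[j]))
                cand = (q, lo, hi)
                if best is None or cand < best:
                    best = cand
                    bi, bj = i, j
        i, j = bi, bj
        li = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li = clamp(li, f"{keys[i]}")
        lj = clamp(lj, f"{keys[j]}")
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        newd = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D2[r - 2, : r - 2] = newd[keep]
        D2[: r - 2, r - 2] = newd[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        D = D2

    # connect the final three nodes through an unrooted (trifurcating) center
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12), keys[0])
    l1 = clamp(0.5 * (d01 + d12 - d02), keys[1])
    l2 = clamp(0.5 * (d02 + d12 - d01), keys[2])
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = ln
    order = np.argsort([keys[0], keys[1], keys[2]], kind="stable")
    root = TreeNode(children=[nodes[k] for k in order])
    return root


def msa_nj_builder(deletion_mode: str = "pairwise") -> Callable[[MSA], TreeNode]:
    """The default tree builder: Poisson-corrected p-distances then NJ."""

    def build(msa: MSA) -> TreeNode:
        return nj_tree(poisson_correct(p_distance(msa, deletion_mode)))

    return build


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each canonicalised as the side that does
    not contain the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = full - below if anchor in below else below
        if 1 < len(side) < len(full) - 1:
            splits.add(frozenset(side))
    return splits


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    """True when two trees share all non-trivial unrooted splits."""
    return tree_splits(t1) == tree_splits(t2)


def bootstrap_support(
    msa: MSA,
    builder: Callable[[MSA], TreeNode] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Column bootstrap with bipartition support.

    Builds the tree on the original alignment, then ``B`` column-resampled
    replicates; each internal edge of the original tree is annotated with
    the percentage of replicates containing its split.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if builder is None:
        builder = msa_nj_builder()
    rng = np.random.default_rng(seed)
    tree = builder(msa)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    L = msa.n_columns
    cols = np.array([list(r) for r in msa.rows])
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        rep_rows = tuple("".join(row) for row in cols[:, idx])
        try:
            rep_tree = builder(MSA(msa.ids, rep_rows))
        except ValueError:
            continue  # e.g. a saturated or incomparable replicate
        for s in tree_splits(rep_tree):
            if s in counts:
                counts[s] += 1
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    for node in tree.non_tips(include_self=False):
        below = {t.name for t in node.tips()}
        side = full - below if anchor in below else below
        key = frozenset(side)
        if key in counts:
            pct = 100.0 * counts[key] / B
            node.support = pct
            node.name = f"{pct:g}"
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree as Newick with branch lengths to 6 decimal places
    and internal-node labels (bootstrap supports) preserved."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree) + ";\n"


def read_newick(text: str) -> TreeNode:
    """Parse Newick text; rejects duplicate leaf names. Internal labels are
    kept as node names (and mirrored to ``support`` when numeric)."""
    tree = TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    names = [t.name for t in tree.tips()]
    dups = {x for x in names if names.count(x) > 1}
    if dups:
        raise ValueError(f"duplicate leaf names in newick: {sorted(dups)}")
    for node in tree.non_tips(include_self=False):
        if node.name:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
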