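"""Neighbor-Joining trees with column-resampling bootstrap support.

The agglomeration is the Saitou–Nei algorithm with the Studier–Keppler
Q criterion. Tie-breaking and negative-branch handling are pinned for
reproducibility: the Q-matrix minimum is taken at the first (row,
column) position in scan order, and a negative branch length is clamped
to zero with the deficit moved onto its sibling branch so path lengths
through the new node are preserved.

Trees are scikit-bio ``TreeNode`` objects and serialize to Newick;
bootstrap supports (percent of replicates containing each bipartition)
are written as internal node names.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from skbio import TreeNode

from .seqdist import AlignedSeqRecord, DistanceMatrix, distance_matrix

__all__ = ["nj_tree", "bootstrap_support", "bipartitions", "is_monophyletic"]


def _join_lengths(dij: float, li: float, lj: float):
    """Clamp a negative branch to 0, transferring the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted Neighbor-Joining tree from a distance matrix."""
    n = len(dm)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimum in row-major scan order over i < j
        iu, ju = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu, ju]))
        i, j = int(iu[k]), int(ju[k])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _join_lengths(d[i, j], li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        dnew = np.delete(dnew, [i, j])
        d = np.delete(np.delete(d, [i, j], axis=0), [i, j], axis=1)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew
        nodes = [x for t, x in enumerate(nodes) if t not in (i, j)] + [parent]

    # final three nodes around an unrooted central vertex
    (a, b, c), dd = nodes, d
    la = 0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2])
    lb = 0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2])
    lc = 0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set, one frozenset per edge.

    Each split is canonicalized as the side NOT containing the
    alphabetically first leaf name.
    """
    leaves = sorted(x.name for x in tree.tips())
    ref = leaves[0]
    full = set(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = {x.name for x in node.tips()}
        if ref in side:
            side = full - side
        if 1 < len(side) < len(full) - 1:
            out.add(frozenset(side))
    return out


def is_monophyletic(tree: TreeNode, names) -> bool:
    """True if ``names`` (or its complement) forms a clade of the unrooted tree."""
    names = frozenset(names)
    full = frozenset(x.name for x in tree.tips())
    comp = full - names
    if len(names) <= 1 or len(comp) <= 1:
        return True
    splits = set()
    ref = sorted(full)[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(x.name for x in node.tips())
        splits.add(side if ref not in side else full - side)
    target = names if ref not in names else comp
    return target in splits


def bootstrap_support(
    records: list[AlignedSeqRecord],
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "k2p",
    gamma_a: float | None = None,
) -> TreeNode:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate alignment gets its own distance matrix and NJ tree, and
    the support of an internal edge of the original tree is the percent
    of replicate trees containing the same bipartition. Supports are
    stored as internal node names (0-100, one decimal).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    if not records or len(records[0].bases) < 1:
        raise ValueError("alignment must have at least one column")
    dm = distance_matrix(records, model=model, gamma_a=gamma_a)
    tree = nj_tree(dm)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}

    rng = np.random.default_rng(seed)
    length = len(records[0].bases)
    base_mat = np.array([np.frombuffer(r.bases.encode(), dtype=np.uint8) for r in records])
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            replace(r, bases=row.tobytes().decode())
            for r, row in zip(records, base_mat[:, cols])
        ]
        rep_splits = bipartitions(nj_tree(distance_matrix(resampled, model=model, gamma_a=gamma_a)))
        for bp in counts:
            if bp in rep_splits:
                counts[bp] += 1

    leaves = sorted(x.name for x in tree.tips())
    ref = leaves[0]
    full = set(leaves)
    for node in tree.non_tips(include_self=False):
        side = {x.name for x in node.tips()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in counts:
            node.name = f"{100.0 * counts[key] / n_reps:.1f}"
    return tree
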