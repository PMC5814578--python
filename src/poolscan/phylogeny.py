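"""Distance-based phylogeny: p-distance, neighbour joining, bootstrap.

Accessions are compared by haploid p-distance (fraction of panel sites
with differing allele codes; optional Jukes-Cantor correction).  Trees
are built with the Saitou-Nei neighbour-joining agglomeration: at each
step the pair minimising the Q-criterion is joined, with exact ties
broken by the lexicographically smallest pair of clade labels so that
output is deterministic and independent of sample order.  Branch supports come from a column
(site) bootstrap: resample sites with replacement, rebuild the tree, and
count how often each internal split of the original tree is recovered.

Trees are scikit-bio ``TreeNode`` objects rooted at the final
trifurcation (an unrooted tree in rooted representation) and serialise
to Newick with bootstrap supports as integer internal-node labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .snv_matrix import GenotypeMatrix

__all__ = [
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "robinson_foulds",
    "write_newick",
    "read_newick",
]


def _pairwise_mismatch(calls: np.ndarray, weights: Optional[np.ndarray] = None):
    """Weighted mismatch counts between binary haploid rows.

    mismatches(x, y) = sum w * (x XOR y) = s_x + s_y - 2 <wx, y> for
    0/1 codes, which keeps the bootstrap O(n^2 m) in BLAS.
    """
    x = calls.astype(np.float64)
    if weights is None:
        weights = np.ones(x.shape[1])
    xw = x * weights
    s = xw.sum(axis=1)
    cross = xw @ x.T
    return s[:, None] + s[None, :] - 2 * cross, float(weights.sum())


def p_distance(
    matrix: GenotypeMatrix, jukes_cantor: bool = False
) -> DistanceMatrix:
    """Fraction of sites at which two accessions differ, as a scikit-bio
    DistanceMatrix.  ``jukes_cantor`` applies d = -3/4 ln(1 - 4p/3)."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if matrix.n_sites == 0:
        raise ValueError("need at least 1 site")
    mism, total = _pairwise_mismatch(matrix.calls)
    d = mism / total
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    if jukes_cantor:
        arg = 1 - 4 * d / 3
        if np.any(arg <= 0):
            raise ValueError("p-distance too large for Jukes-Cantor correction")
        d = -0.75 * np.log(arg)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=matrix.samples)


def _nj_from_array(d: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Saitou-Nei NJ on a dense distance array.

    Exact ties on the Q-criterion (common with rational p-distances) are
    broken by the lexicographically smallest pair of clade labels, where
    a clade's label is the smallest leaf name it contains: deterministic
    and invariant to the input row order.
    """
    nodes = [TreeNode(name=name) for name in ids]
    keys = [str(name) for name in ids]  # min leaf name per active clade
    d = d.astype(np.float64, copy=True)
    while len(nodes) > 3:
        r = len(nodes)
        rowsum = d.sum(axis=1)
        q = (r - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(r, k=1)
        qmin = q[iu].min()
        ties = np.flatnonzero(q[iu] == qmin)
        i, j = min(
            ((int(iu[0][k]), int(iu[1][k])) for k in ties),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        li = d[i, j] / 2 + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        dnew = (d[i] + d[j] - d[i, j]) / 2
        keep = [x for x in range(r) if x not in (i, j)]
        d2 = np.empty((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        new_key = min(keys[i], keys[j])
        keys = [keys[x] for x in keep] + [new_key]
        nodes = [nodes[x] for x in keep] + [parent]
    root = TreeNode()
    if len(nodes) == 3:
        dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
        lengths = [(dab + dac - dbc) / 2, (dab + dbc - dac) / 2,
                   (dac + dbc - dab) / 2]
    else:  # exactly 2 nodes can only arise from a 2-taxon call, rejected below
        raise AssertionError("unreachable")
    for node, length in zip(nodes, lengths):
        node.length = float(length)
        root.append(node)
    return root


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = False
) -> TreeNode:
    """Neighbour-joining tree from a distance matrix (>= 3 taxa).

    Branch lengths may come out slightly negative on noisy distances;
    ``clamp_negative`` floors them at 0 (as common GUI tools do)."""
    if dm.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    tree = _nj_from_array(np.asarray(dm.data), list(dm.ids))
    if clamp_negative:
        for node in tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of an unrooted tree as canonical leaf-name sets.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf name is kept, so the encoding is
    invariant to leaf order and rooting at the trifurcation.
    """
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    full = frozenset(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(full) - 2:
            continue  # trivial split
        if ref in side:
            side = full - side
        splits.add(side)
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference (Robinson-Foulds) distance between unrooted
    trees over identical leaf sets."""
    s1, s2 = bipartitions(t1), bipartitions(t2)
    return len(s1 ^ s2)


def bootstrap_support(
    matrix: GenotypeMatrix,
    replicates: int = 1000,
    seed: Optional[int] = None,
    jukes_cantor: bool = False,
    clamp_negative: bool = False,
) -> TreeNode:
    """NJ tree with column-bootstrap supports on internal nodes.

    Sites are resampled with replacement ``replicates`` times; support is
    100 x (replicates recovering the split) / replicates, serialised as
    integer internal-node labels.  The random stream draws only column
    indices, so supports are invariant to sample order for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(p_distance(matrix, jukes_cantor=jukes_cantor),
                            clamp_negative=clamp_negative)
    target = {split: 0 for split in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    m = matrix.n_sites
    for _ in range(replicates):
        counts = np.bincount(rng.integers(0, m, size=m), minlength=m)
        mism, total = _pairwise_mismatch(matrix.calls, counts.astype(float))
        d = mism / total
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        if jukes_cantor:
            d = -0.75 * np.log(np.maximum(1 - 4 * d / 3, 1e-12))
            np.fill_diagonal(d, 0.0)
        rep = _nj_from_array(d, matrix.samples)
        rep_splits = bipartitions(rep)
        for split in target:
            if split in rep_splits:
                target[split] += 1

    full = frozenset(s for s in matrix.samples)
    ref = min(matrix.samples)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        key = full - side if ref in side else side
        if key in target:
            node.name = str(round(100 * target[key] / replicates))
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialise to Newick with branch lengths (and supports as
    internal-node labels when present); round-trips losslessly."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
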