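"""Phylogenetic context: p-distances, neighbor joining, clade assignment.

Distances are uncorrected p-distances (fraction of mismatching residue
pairs over comparable columns); trees come from the classical
neighbor-joining algorithm of Saitou & Nei, which is exact on additive
distance matrices.  Clades are assigned by proximity to characterized
reference leaves.  Trees are ``skbio.TreeNode`` objects, so Newick I/O
and patristic distances use scikit-bio directly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seqio import GAP, Alignment

PDistanceMode = str  # "pairwise" (pairwise deletion) | "complete" (complete deletion)


def p_distance_matrix(alignment: Alignment, mode: str = "pairwise") -> DistanceMatrix:
    """Pairwise p-distances between all sequences of an alignment.

    ``pairwise`` mode drops, per pair, only the columns where either
    sequence is gapped; ``complete`` mode drops every column containing a
    gap in any sequence before comparing.  A pair with zero comparable
    columns is an error (its distance is undefined).
    """
    if mode not in ("pairwise", "complete"):
        raise ValueError(f"mode must be 'pairwise' or 'complete', got {mode!r}")
    ids = alignment.ids
    chars = np.array([list(rec.residues) for rec in alignment.records])
    nongap = chars != GAP
    if mode == "complete":
        keep = nongap.all(axis=0)
        if not keep.any():
            raise ValueError("no gap-free columns for complete-deletion distances")
        chars, nongap = chars[:, keep], nongap[:, keep]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no comparable columns"
                )
            d[i, j] = d[j, i] = np.count_nonzero(
                chars[i, comparable] != chars[j, comparable]
            ) / m
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining on a symmetric distance matrix.

    Produces an unrooted tree (trifurcating root) whose leaf-to-leaf path
    lengths reproduce the input exactly when the input is additive.
    Negative branch-length estimates are clamped to zero with the deficit
    moved onto the sibling edge, which preserves the path length through
    the joined pair.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / zero diagonal
    if np.any(np.asarray(dm.data) < 0):
        raise ValueError("distance matrix has negative entries")
    n = dm.shape[0]
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")

    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=str(label)) for label in dm.ids]

    def attach(child: TreeNode, parent: TreeNode, length: float) -> None:
        child.length = float(length)
        parent.append(child)

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        # Q-criterion: q_ij = (m - 2) d_ij - r_i - r_j
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        # clamp a negative estimate, shifting the deficit onto the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        attach(nodes[i], parent, li)
        attach(nodes[j], parent, lj)
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the last three nodes around an unrooted center (three-point formulas)
    root = TreeNode()
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (l0, l1, l2)):
        attach(node, root, max(length, 0.0))
    return root


def path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf patristic distances of a tree."""
    return tree.tip_tip_distances()


def assign_clades(tree: TreeNode, references: Mapping[str, str]) -> dict[str, str]:
    """Label every leaf with the clade of its nearest reference leaf.

    ``references`` maps reference leaf names to clade names.  Nearness is
    patristic (path-length) distance; ties go to the lexicographically
    smallest clade name.  References map to their own clade.
    """
    if not references:
        raise ValueError("need at least one reference leaf")
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(references) - tips)
    if missing:
        raise KeyError(f"reference leaves not in tree: {missing}")
    dm = tree.tip_tip_distances()
    assignment: dict[str, str] = {}
    for leaf in dm.ids:
        best = min(
            (dm[leaf, ref], clade) for ref, clade in references.items()
        )
        assignment[leaf] = best[1]
    for ref, clade in references.items():
        assignment[ref] = clade
    return assignment


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
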