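"""Simple-matching genetic distance, neighbour-joining trees, and PCoA.

Distance between two accessions is one minus the simple matching
coefficient: the fraction of loci, non-missing in both, at which the two
genotype states (dose 0/1/2) coincide.  Trees are built with the classic
Saitou–Nei neighbour-joining algorithm with deterministic tie-breaking, and
ordination is principal coordinates analysis (Gower double-centering of the
squared distances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("wheatpopgen")

#: below this many comparable loci a pairwise distance is considered shaky
MIN_COMPARABLE_LOCI = 10


def simple_matching_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - simple-matching-coefficient over genotype states.

    Missing calls are excluded pairwise; a pair with zero comparable loci is
    an error (naming the pair), and pairs with fewer than 10 comparable loci
    are flagged in the log.
    """
    d = gm.doses
    nonmiss = (d != MISSING).astype(np.float64)
    comparable = nonmiss @ nonmiss.T
    matches = np.zeros_like(comparable)
    for state in (0, 1, 2):
        ind = (d == state).astype(np.float64)
        matches += ind @ ind.T
    if (comparable == 0).any():
        i, j = np.argwhere(comparable == 0)[0]
        raise ValueError(
            f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share no "
            "comparable loci"
        )
    n_shaky = int((np.triu(comparable, 1) < MIN_COMPARABLE_LOCI)[
        np.triu_indices(gm.n_samples, 1)].sum())
    if n_shaky:
        logger.warning("%d sample pairs have < %d comparable loci",
                       n_shaky, MIN_COMPARABLE_LOCI)
    dist = 1.0 - matches / comparable
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # remove float asymmetry
    return DistanceMatrix(dist, ids=gm.sample_ids)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining; returns an unrooted tree with a
    trifurcating root.

    The pair minimising Q(i,j) = (m-2) d(i,j) - R_i - R_j is joined at each
    step; exact ties break on the lexicographically smallest index pair in
    the current node order.  A negative branch length is clamped to zero and
    its deficit moved to the sister branch, preserving the path length
    between the joined nodes.
    """
    D = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=i) for i in dm.ids]
    m = len(nodes)
    if m < 3:
        raise ValueError("neighbour joining needs at least 3 samples")
    while m > 3:
        R = D.sum(axis=1)
        Qm = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Qm, np.inf)
        # lexicographically-smallest argmin pair
        flat = int(np.argmin(Qm))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.empty((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = d_new[keep]
        D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        D = D_next
        nodes = [nodes[k] for k in keep] + [parent]
        m -= 1
    # final trifurcation
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode()
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
        root.append(node)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity check)."""
    return tree.tip_tip_distances()


def main_split(tree: TreeNode, min_fraction: float = 0.2) -> set[str]:
    """The tree's main division: leaves on one side of the longest internal
    edge whose removal leaves at least *min_fraction* of the leaves on each
    side.

    Long edges subtending tiny cherries are ignored; the returned set and
    its complement are the two top-level clusters of the dendrogram.
    """
    n = sum(1 for _ in tree.tips())
    best, best_len = None, -np.inf
    for node in tree.non_tips(include_self=False):
        size = sum(1 for _ in node.tips())
        if min(size, n - size) < min_fraction * n:
            continue
        if (node.length or 0.0) > best_len:
            best, best_len = node, node.length or 0.0
    if best is None:
        raise ValueError("no internal edge gives a balanced split")
    return {t.name for t in best.tips()}


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Principal-coordinate embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray = field(repr=False)       # (n, n_axes)
    eigenvalues: np.ndarray = field(repr=False)       # positive, descending
    proportion_explained: np.ndarray = field(repr=False)
    negative_eigenvalues: np.ndarray = field(repr=False)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical multidimensional scaling of a distance matrix.

    Gower-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.  Negative eigenvalues —
    possible because simple-matching distances need not be Euclidean — are
    excluded from the variance proportions and reported separately.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * n * np.finfo(float).eps
    pos = vals > tol
    neg = vals[vals < -tol]
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalue: degenerate distances")
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues",
                       n_axes, n_pos)
        n_axes = n_pos
    ev = vals[:n_axes]
    coords = vecs[:, :n_axes] * np.sqrt(ev)
    coords -= coords.mean(axis=0)  # centroid at origin (numerically)
    return PCoAResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=vals[pos],
        proportion_explained=vals[pos] / vals[pos].sum(),
        negative_eigenvalues=neg,
    )
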