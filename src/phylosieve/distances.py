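"""Composition-robust pairwise distances and neighbour joining.

LogDet (paralinear) distances are consistent under arbitrarily varying
stationary composition across lineages, which is what makes them a useful
desk-scale check when compositional attraction is suspected.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .likelihood import encode_alignment
from .trees import Node, Tree


def logdet_distance(aln: Alignment) -> np.ndarray:
    """Pairwise LogDet/paralinear distance matrix.

    Zero cells of each pairwise joint count matrix get a 0.5 pseudocount.
    Pairs sharing no ungapped columns are flagged ``nan``.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    k = len(aln.symbols)
    codes = encode_alignment(aln)
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            if not ok.any():
                D[i, j] = D[j, i] = np.nan
                continue
            J = np.zeros((k, k))
            np.add.at(J, (codes[i][ok], codes[j][ok]), 1.0)
            J[J == 0] = 0.5
            F = J / J.sum()
            fx = F.sum(axis=1)
            fy = F.sum(axis=0)
            sign, logdet = np.linalg.slogdet(F)
            if sign <= 0:
                D[i, j] = D[j, i] = np.nan
                continue
            d = -(logdet - 0.5 * (np.log(fx).sum() + np.log(fy).sum())) / k
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


def nj_tree(matrix: np.ndarray, taxa: list[str]) -> Tree:
    """Neighbour joining with deterministic lowest-index tie-breaking.

    Returns an unrooted tree (trifurcating root for n >= 3).
    """
    D = np.asarray(matrix, dtype=float)
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("matrix does not match taxon list")
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries")
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [Node(label=t) for t in taxa]
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best[0], best[1]] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            D[new_idx, c] = D[c, new_idx] = 0.5 * (D[i, c] + D[j, c] - dij)
        active = [c for c in active if c not in (i, j)] + [new_idx]
    root = Node()
    if len(active) == 3:
        i, j, k3 = active
        dij, dik, djk = D[i, j], D[i, k3], D[j, k3]
        nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
        nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
        nodes[k3].length = max(0.5 * (dik + djk - dij), 0.0)
        for c in active:
            root.add_child(nodes[c])
    elif len(active) == 2:
        i, j = active
        nodes[i].length = D[i, j] / 2
        nodes[j].length = D[i, j] / 2
        for c in active:
            root.add_child(nodes[c])
    else:
        root = nodes[active[0]]
    return Tree(root, rooted=False)
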