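"""Per-taxon compositional diagnostics.

Compositional convergence between phylogenetically distant lineages (for
example between unrelated hyperthermophiles) is a classic driver of
artefactual attraction in concatenated trees.  This module quantifies it:
per-taxon state frequencies, a per-taxon chi-square heterogeneity
statistic, pairwise compositional distances, and a UPGMA ordering for
heatmap-style reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .alignment import Alignment
from .likelihood import encode_alignment
from .trees import Node, Tree


@dataclass
class CompositionTable:
    taxa: list[str]
    symbols: str
    frequencies: np.ndarray   # (n_taxa, k), rows sum to 1
    counts: np.ndarray        # ungapped symbol count per taxon
    mean: np.ndarray          # unweighted across-taxon mean frequencies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=self.taxa,
                            columns=list(self.symbols))


def taxon_composition(aln: Alignment) -> CompositionTable:
    """State frequencies per taxon over non-gap, non-missing cells."""
    if aln.n_taxa == 0 or aln.n_cols == 0:
        raise ValueError("empty alignment")
    codes = encode_alignment(aln)
    k = len(aln.symbols)
    freqs = np.zeros((aln.n_taxa, k))
    counts = np.zeros(aln.n_taxa)
    for i, taxon in enumerate(aln.taxa):
        row = codes[i][codes[i] >= 0]
        if row.size == 0:
            raise ValueError(f"taxon {taxon!r} has no ungapped symbols")
        counts[i] = row.size
        freqs[i] = np.bincount(row, minlength=k) / row.size
    return CompositionTable(list(aln.taxa), aln.symbols, freqs, counts,
                            freqs.mean(axis=0))


def composition_chisq(table: CompositionTable):
    """Per-taxon chi-square against the unweighted mean composition:
    X2_t = N_t * sum_s (f_ts - fbar_s)^2 / fbar_s, plus the total."""
    fbar = table.mean
    present = fbar > 0
    if np.any(~present):
        for i in range(table.frequencies.shape[0]):
            if np.any(table.frequencies[i, ~present] > 0):
                raise ValueError("taxon uses a state with zero mean frequency")
    dev = (table.frequencies[:, present] - fbar[present]) ** 2 / fbar[present]
    per_taxon = table.counts * dev.sum(axis=1)
    return pd.Series(per_taxon, index=table.taxa, name="X2"), float(per_taxon.sum())


def composition_distance(table: CompositionTable, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise distance matrix between taxon compositions.

    ``jensen_shannon`` is the square-root JS divergence (a metric).
    """
    n = len(table.taxa)
    D = np.zeros((n, n))
    if metric == "euclidean":
        diff = table.frequencies[:, None, :] - table.frequencies[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
    elif metric == "jensen_shannon":
        for i in range(n):
            for j in range(i + 1, n):
                d = jensenshannon(table.frequencies[i], table.frequencies[j], base=np.e)
                D[i, j] = D[j, i] = 0.0 if np.isnan(d) else float(d)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D


def mutual_nearest_neighbours(D: np.ndarray, i: int, j: int) -> bool:
    """Whether taxa i and j are each other's compositional nearest
    neighbour (self excluded)."""
    masked = D.copy().astype(float)
    np.fill_diagonal(masked, np.inf)
    return int(np.argmin(masked[i])) == j and int(np.argmin(masked[j])) == i


def upgma_order(matrix: np.ndarray, taxa: list[str]):
    """UPGMA dendrogram with smallest-index tie-breaking.

    Returns (tree, leaf order) for deterministic heatmap ordering.
    """
    D = np.asarray(matrix, dtype=float)
    n = len(taxa)
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("matrix must be symmetric and match the taxon list")
    nodes = [Node(label=t, length=0.0) for t in taxa]
    heights = [0.0] * n
    sizes = [1] * n
    active = list(range(n))
    D = D.copy()
    while len(active) > 1:
        best = None
        for a_pos, a in enumerate(active):
            for b in active[a_pos + 1:]:
                if best is None or D[a, b] < D[best[0], best[1]] - 1e-12:
                    best = (a, b)
        i, j = best
        h = D[i, j] / 2.0
        parent = Node()
        for c in (i, j):
            nodes[c].length = max(h - heights[c], 0.0)
            parent.add_child(nodes[c])
        new = len(nodes)
        nodes.append(parent)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            D[new, c] = D[c, new] = (sizes[i] * D[i, c] + sizes[j] * D[j, c]) / (sizes[i] + sizes[j])
        active = [c for c in active if c not in (i, j)] + [new]
    tree = Tree(nodes[active[0]], rooted=True)
    order = [leaf.label for leaf in tree.leaves()]
    return tree, order
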