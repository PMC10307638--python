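"""Felsenstein pruning on fixed trees, with branch-length optimisation.

Conditional likelihood vectors are computed per gamma-rate category with
per-site log rescaling, so long alignments and deep trees do not
underflow.  Gap and missing cells are fully ambiguous.  The same inside /
outside vector machinery drives the one-branch likelihood curves used by
the coordinate-ascent branch-length optimiser and by candidate placement.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .models import SubstitutionModel
from .trees import Node, Tree

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0


class LikelihoodError(ValueError):
    pass


def encode_alignment(aln: Alignment, symbols: str | None = None) -> np.ndarray:
    """Integer codes per cell; -1 marks gap/missing/ambiguous."""
    symbols = symbols or aln.symbols
    lookup = {s: i for i, s in enumerate(symbols)}
    codes = np.full(aln.data.shape, -1, dtype=np.int32)
    for sym, i in lookup.items():
        codes[aln.data == sym] = i
    return codes


class PruningEngine:
    """Binds an alignment, a tree and a model for repeated likelihood work."""

    def __init__(self, aln: Alignment, tree: Tree, model: SubstitutionModel):
        if model.k != len(aln.symbols):
            raise LikelihoodError(
                f"model has {model.k} states but alphabet {aln.alphabet!r} has "
                f"{len(aln.symbols)}"
            )
        self.aln = aln
        self.tree = tree
        self.model = model
        self.nodes: list[Node] = tree.postorder()
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        self.leaf_codes = {}
        codes = encode_alignment(aln)
        for node in self.nodes:
            if node.is_leaf:
                if node.label not in taxon_row:
                    raise LikelihoodError(f"tree leaf {node.label!r} absent from alignment")
                self.leaf_codes[id(node)] = codes[taxon_row[node.label]]
            elif node is not tree.root and node.length is None:
                raise LikelihoodError("internal node without branch length")
        self.L = aln.n_cols
        self.rates = model.category_rates()
        self.n_cat = len(self.rates)

    # -- inside (upward) pass ---------------------------------------------
    def _leaf_contrib(self, node: Node, P: np.ndarray) -> np.ndarray:
        codes = self.leaf_codes[id(node)]
        out = np.ones((self.model.k, self.L))
        mask = codes >= 0
        out[:, mask] = P[:, codes[mask]]
        return out

    def inside(self):
        """Conditional vectors B[node][cat] (k, L) with log-scalers (L,)."""
        B = {}
        scale = {}
        for node in self.nodes:
            if node.is_leaf:
                continue
            vecs, scl = [], []
            for c, r in enumerate(self.rates):
                acc = np.ones((self.model.k, self.L))
                s = np.zeros(self.L)
                for child in node.children:
                    P = self.model.transition(child.length, r)
                    if child.is_leaf:
                        acc *= self._leaf_contrib(child, P)
                    else:
                        acc *= P @ B[id(child)][c]
                        s += scale[id(child)][c]
                m = acc.max(axis=0)
                if np.any(m <= 0):
                    raise LikelihoodError("zero site likelihood encountered")
                acc /= m
                s = s + np.log(m)
                vecs.append(acc)
                scl.append(s)
            B[id(node)] = vecs
            scale[id(node)] = scl
        return B, scale

    def per_category_site_loglik(self, inside_cache=None) -> np.ndarray:
        """(n_cat, L) log site likelihoods (equal category priors not applied)."""
        B, scale = inside_cache or self.inside()
        pi = self.model.frequencies
        root = self.tree.root
        out = np.empty((self.n_cat, self.L))
        if root.is_leaf:
            raise LikelihoodError("tree must have at least one internal node")
        for c in range(self.n_cat):
            lik = pi @ B[id(root)][c]
            out[c] = np.log(lik) + scale[id(root)][c]
        return out

    def loglik(self) -> tuple[float, np.ndarray]:
        percat = self.per_category_site_loglik()
        per_site = logsumexp(percat, axis=0) - np.log(self.n_cat)
        return float(per_site.sum()), per_site

    # -- outside vectors ----------------------------------------------------
    def edge_outside(self, inside_cache=None):
        """For each non-root node v, the conditional of everything outside
        the subtree of v, evaluated at the parent end of v's branch
        (stationary frequencies included at the root)."""
        B, scale = inside_cache or self.inside()
        pi = self.model.frequencies
        out, oscale = {}, {}
        root = self.tree.root
        root_out = [np.tile(pi[:, None], (1, self.L)) for _ in range(self.n_cat)]
        root_scale = [np.zeros(self.L) for _ in range(self.n_cat)]
        node_out = {id(root): root_out}
        node_scale = {id(root): root_scale}
        for node in self.tree.preorder():
            if node.is_leaf and node is not root:
                pass
            for child in node.children:
                vecs, scl = [], []
                for c, r in enumerate(self.rates):
                    acc = node_out[id(node)][c].copy()
                    s = node_scale[id(node)][c].copy()
                    for sib in node.children:
                        if sib is child:
                            continue
                        P = self.model.transition(sib.length, r)
                        if sib.is_leaf:
                            acc *= self._leaf_contrib(sib, P)
                        else:
                            acc *= P @ B[id(sib)][c]
                            s += scale[id(sib)][c]
                    m = acc.max(axis=0)
                    acc /= m
                    s = s + np.log(m)
                    vecs.append(acc)
                    scl.append(s)
                out[id(child)] = vecs
                oscale[id(child)] = scl
                if not child.is_leaf:
                    below, bscl = [], []
                    for c, r in enumerate(self.rates):
                        P = self.model.transition(child.length, r)
                        vec = P.T @ vecs[c]
                        m = vec.max(axis=0)
                        below.append(vec / m)
                        bscl.append(scl[c] + np.log(m))
                    node_out[id(child)] = below
                    node_scale[id(child)] = bscl
        return (B, scale), (out, oscale)

    def edge_loglik_fn(self, node: Node, caches):
        """Total log-likelihood as a function of node's branch length."""
        (B, scale), (out, oscale) = caches
        ov, os_ = out[id(node)], oscale[id(node)]
        k = self.model.k

        def fn(t: float) -> float:
            percat = np.empty((self.n_cat, self.L))
            for c, r in enumerate(self.rates):
                P = self.model.transition(t, r)
                if node.is_leaf:
                    below = self._leaf_contrib(node, P)
                    s = np.zeros(self.L)
                else:
                    below = P @ B[id(node)][c]
                    s = scale[id(node)][c]
                lik = np.einsum("kl,kl->l", ov[c], below)
                percat[c] = np.log(np.maximum(lik, 1e-300)) + s + os_[c]
            return float((logsumexp(percat, axis=0) - np.log(self.n_cat)).sum())

        return fn


def felsenstein_loglik(aln: Alignment, tree: Tree, model: SubstitutionModel):
    """Total and per-site log-likelihood on a fixed tree."""
    return PruningEngine(aln, tree, model).loglik()


def optimize_branch_lengths(tree: Tree, aln: Alignment, model: SubstitutionModel,
                            tol: float = 1e-4, max_sweeps: int = 50):
    """Coordinate-ascent ML branch lengths (Brent per branch, exact sweeps).

    Returns a new tree and its log-likelihood; the input tree is untouched.
    """
    work = tree.copy()
    for node in work.postorder():
        if node is not work.root and (node.length is None or node.length <= 0):
            node.length = 0.05
    current, _ = felsenstein_loglik(aln, work, model)
    for _ in range(max_sweeps):
        for node in work.postorder():
            if node is work.root:
                continue
            engine = PruningEngine(aln, work, model)
            caches = engine.edge_outside()
            fn = engine.edge_loglik_fn(node, caches)
            res = minimize_scalar(lambda t: -fn(t), bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded", options={"xatol": 1e-5})
            if -res.fun > fn(node.length):
                node.length = float(res.x)
        new, _ = felsenstein_loglik(aln, work, model)
        if new - current < tol:
            current = max(new, current)
            break
        current = new
    return work, current
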