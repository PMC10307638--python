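"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own algorithmic paths:
likelihoods by exhaustive enumeration over internal states, the DTL model
by enumeration of the generative process truncated at a fixed number of
duplication/transfer/loss events, and the signed-rank null by direct
enumeration of sign assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

from phylosieve.likelihood import encode_alignment
from phylosieve.reconcile import _FamilyDP, species_of_leaf


def brute_force_loglik(aln, tree, model) -> float:
    """Sum over all internal-state assignments, column by column."""
    codes = encode_alignment(aln)
    k = model.k
    pi = model.frequencies
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    rates = model.category_rates()
    row = {t: i for i, t in enumerate(aln.taxa)}
    total = 0.0
    for site in range(aln.n_cols):
        lik_cats = []
        for r in rates:
            P = {id(n): model.transition(n.length, r)
                 for n in nodes if n.length is not None}
            s = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                p = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    parent_state = amap[id(n.parent)]
                    if n.is_leaf:
                        c = codes[row[n.label]][site]
                        p *= 1.0 if c < 0 else P[id(n)][parent_state, c]
                    else:
                        p *= P[id(n)][parent_state, amap[id(n)]]
                s += p
            lik_cats.append(s)
        total += np.log(np.mean(lik_cats))
    return total


def brute_force_percat_site_lik(aln, tree, model) -> np.ndarray:
    """Per-category, per-site likelihoods by enumeration (n_cat, L)."""
    codes = encode_alignment(aln)
    k = model.k
    pi = model.frequencies
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    rates = model.category_rates()
    row = {t: i for i, t in enumerate(aln.taxa)}
    out = np.zeros((len(rates), aln.n_cols))
    for ci, r in enumerate(rates):
        P = {id(n): model.transition(n.length, r)
             for n in nodes if n.length is not None}
        for site in range(aln.n_cols):
            s = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                p = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    ps = amap[id(n.parent)]
                    if n.is_leaf:
                        c = codes[row[n.label]][site]
                        p *= 1.0 if c < 0 else P[id(n)][ps, c]
                    else:
                        p *= P[id(n)][ps, amap[id(n)]]
                s += p
            out[ci, site] = s
    return out


def truncated_dtl_loglik(family, stree, rates, budget: int = 10) -> float:
    """Likelihood of a gene family by enumerating the generative process
    with at most ``budget`` duplication+transfer+loss events."""
    p_s, p_d, p_t, p_l = rates.event_probs
    nb = stree.n_branches
    dp = _FamilyDP(family, stree)
    splits = dp.ccp.splits

    ext_memo: dict = {}

    def ext(e: int, j: int) -> float:
        key = (e, j)
        if key in ext_memo:
            return ext_memo[key]
        val = 0.0
        ch = stree.children[e]
        if ch is None:
            if j == 0:
                val += p_s * stree.missing[e]
        else:
            f, g = ch
            val += p_s * sum(ext(f, j1) * ext(g, j - j1) for j1 in range(j + 1))
        if j >= 1:
            if j == 1:
                val += p_l
            val += p_d * sum(ext(e, j1) * ext(e, j - 1 - j1) for j1 in range(j))
            for h in range(nb):
                if h == e:
                    continue
                val += p_t / (nb - 1) * sum(
                    ext(e, j1) * ext(h, j - 1 - j1) for j1 in range(j))
        ext_memo[key] = val
        return val

    p_memo: dict = {}

    def pr(clade: frozenset, e: int, j: int) -> float:
        key = (clade, e, j)
        if key in p_memo:
            return p_memo[key]
        val = 0.0
        ch = stree.children[e]
        if len(clade) == 1:
            leaf = stree.leaf_index[species_of_leaf(next(iter(clade)))]
            if ch is None and e == leaf and j == 0:
                val += p_s * (1 - stree.missing[e])
        if ch is not None:
            f, g = ch
            if len(clade) > 1:
                for a, b, q in splits[clade]:
                    for j1 in range(j + 1):
                        val += p_s * q * (pr(a, f, j1) * pr(b, g, j - j1)
                                          + pr(a, g, j1) * pr(b, f, j - j1))
            for j1 in range(j + 1):
                val += p_s * (pr(clade, f, j1) * ext(g, j - j1)
                              + pr(clade, g, j1) * ext(f, j - j1))
        if j >= 1:
            if len(clade) > 1:
                for a, b, q in splits[clade]:
                    for j1 in range(j):
                        val += p_d * q * 2 * pr(a, e, j1) * pr(b, e, j - 1 - j1)
                    for h in range(nb):
                        if h == e:
                            continue
                        for j1 in range(j):
                            val += p_t * q / (nb - 1) * (
                                pr(a, e, j1) * pr(b, h, j - 1 - j1)
                                + pr(b, e, j1) * pr(a, h, j - 1 - j1))
            for j1 in range(j):
                val += p_d * 2 * pr(clade, e, j1) * ext(e, j - 1 - j1)
            for h in range(nb):
                if h == e:
                    continue
                for j1 in range(j):
                    val += p_t / (nb - 1) * (pr(clade, e, j1) * ext(h, j - 1 - j1)
                                             + pr(clade, h, j1) * ext(e, j - 1 - j1))
        p_memo[key] = val
        return val

    root = frozenset(dp.ccp.leaves)
    lik = np.mean([sum(pr(root, e, j) for j in range(budget + 1))
                   for e in range(nb)])
    return float(np.log(lik))


def enumerate_signed_rank_p(values, reference: float) -> float:
    """Two-sided one-sample signed-rank p by enumerating all 2^n sign
    assignments (midranks for tied magnitudes); n must be small."""
    d = np.asarray(values, dtype=float) - reference
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count_le = count_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count_le += w <= w_obs + 1e-12
        count_ge += w >= w_obs - 1e-12
    total = 2 ** n
    return min(1.0, 2.0 * min(count_le / total, count_ge / total))
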