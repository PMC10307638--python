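"""Undated duplication–transfer–loss (DTL) reconciliation.

The model: a gene lineage on a species-tree branch draws one event —
speciation-or-leaf-arrival, duplication, transfer or loss — with
probabilities ``P_S = 1/Z``, ``P_D = delta/Z``, ``P_T = tau/Z``,
``P_L = lambda/Z`` (``Z = 1 + delta + tau + lambda``).  Transfers are
undated: the recipient is any other branch, uniformly.  At a leaf, each
arriving copy is observed with probability ``1 - m`` where ``m`` is the
genome's missing fraction (one minus its estimated completeness), so
genome incompleteness is part of the probabilistic model rather than a
post-hoc filter.

The per-gene-node dynamic program couples all species branches (through
transfers and speciation-loss), so each gene node is resolved by one small
linear solve instead of fixed-point iteration.  Reconciliations are drawn
by stochastic backtracking of the same program.  Expected copy numbers are
corrected for extinction by adding, wherever the sampler invokes an
extinction probability, the expected copies and events of the unsampled
("ghost") sub-lineage — computed from the same linear operator — so the
correction places mass on exactly the branches the observed gene tree
cannot see, rather than rescaling the visible ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .trees import Node, Tree

THETA_EVENT = 0.3
THETA_PRESENT = 0.3
THETA_MAYBE = 0.1


class ReconciliationError(ValueError):
    pass


@dataclass(frozen=True)
class DTLRates:
    duplication: float
    transfer: float
    loss: float

    def __post_init__(self):
        for name, v in (("duplication", self.duplication), ("transfer", self.transfer),
                        ("loss", self.loss)):
            if not np.isfinite(v) or v < 0:
                raise ReconciliationError(f"{name} rate must be finite and non-negative")

    @property
    def event_probs(self):
        z = 1.0 + self.duplication + self.transfer + self.loss
        return (1.0 / z, self.duplication / z, self.transfer / z, self.loss / z)


class SpeciesTree:
    """Rooted binary species tree with postorder branch indices 0..2n-2
    (the root branch included) and per-leaf missing fractions."""

    def __init__(self, tree: Tree, missing: dict[str, float] | None = None):
        self.tree = tree
        self.nodes = tree.postorder()
        for node in self.nodes:
            if node.children and len(node.children) != 2:
                raise ReconciliationError("species tree must be binary")
        self.n_branches = len(self.nodes)
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            (self.index[id(n.children[0])], self.index[id(n.children[1])])
            if n.children else None
            for n in self.nodes
        ]
        self.leaf_index = {n.label: self.index[id(n)] for n in self.nodes if n.is_leaf}
        self.missing = np.zeros(self.n_branches)
        missing = missing or {}
        for label, m in missing.items():
            if label not in self.leaf_index:
                raise ReconciliationError(f"missing fraction for unknown genome {label!r}")
            if not 0.0 <= m < 1.0:
                raise ReconciliationError(f"missing fraction for {label!r} outside [0, 1)")
            self.missing[self.leaf_index[label]] = m
        self.root_index = self.index[id(tree.root)]
        self.branch_names = [
            n.label if n.is_leaf else "|".join(sorted(
                leaf.label for leaf in _clade_leaves(n)))
            for n in self.nodes
        ]

    @classmethod
    def from_completeness(cls, tree: Tree, completeness: dict[str, float]) -> "SpeciesTree":
        """Missing fractions computed as 1 - completeness (fractional)."""
        return cls(tree, {g: 1.0 - c for g, c in completeness.items()})

    def ancestors_of(self, branch: int) -> set[int]:
        anc = set()
        node = self.nodes[branch].parent
        while node is not None:
            anc.add(self.index[id(node)])
            node = node.parent
        return anc

    def leaves_below(self, branch: int) -> set[str]:
        return {n.label for n in _clade_leaves(self.nodes[branch])}


def _clade_leaves(node: Node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


# -- gene families ---------------------------------------------------------

def species_of_leaf(label: str) -> str:
    """Gene copies are named ``genome|i``; a bare genome name maps to itself."""
    return label.split("|")[0]


@dataclass
class GeneFamily:
    family_id: str
    copy_counts: dict[str, int]
    tree: Tree | None = None
    unrooted: bool = False

    def __post_init__(self):
        if any(c < 0 for c in self.copy_counts.values()):
            raise ReconciliationError("copy counts must be non-negative")
        if self.size < 1:
            raise ReconciliationError("family must contain at least one gene")

    @property
    def size(self) -> int:
        return sum(self.copy_counts.values())

    def resolved_tree(self) -> Tree:
        """The gene tree, or a deterministic caterpillar built from the copy
        profile for tree-less (size 2-3) families."""
        if self.tree is not None:
            return _resolve_multifurcations(self.tree)
        labels = []
        for genome in sorted(self.copy_counts):
            for i in range(self.copy_counts[genome]):
                labels.append(f"{genome}|{i+1}" if self.copy_counts[genome] > 1 else genome)
        return _caterpillar(labels)

    @classmethod
    def from_tree(cls, family_id: str, tree: Tree, unrooted: bool = False) -> "GeneFamily":
        counts: dict[str, int] = {}
        for label in tree.leaf_labels():
            sp = species_of_leaf(label)
            counts[sp] = counts.get(sp, 0) + 1
        return cls(family_id, counts, tree, unrooted)


def _caterpillar(labels: list[str]) -> Tree:
    if len(labels) == 1:
        return Tree(Node(label=labels[0]))
    node = Node()
    node.add_child(Node(label=labels[0]))
    node.add_child(Node(label=labels[1]))
    for label in labels[2:]:
        new = Node()
        new.add_child(node)
        new.add_child(Node(label=label))
        node = new
    return Tree(node)


def _resolve_multifurcations(tree: Tree) -> Tree:
    tree = tree.copy()
    for node in tree.postorder():
        while len(node.children) > 2:
            node.children.sort(key=lambda c: min(x.label for x in _clade_leaves(c)))
            a = node.children.pop(0)
            b = node.children.pop(0)
            joint = Node()
            joint.add_child(a)
            joint.add_child(b)
            joint.parent = node
            node.children.insert(0, joint)
    return Tree(tree.root, tree.rooted)


# -- conditional clade probabilities --------------------------------------

@dataclass
class CCPSet:
    """Observed clades with frequencies and conditional split frequencies."""

    leaves: frozenset
    clade_freq: dict[frozenset, float]
    splits: dict[frozenset, list[tuple[frozenset, frozenset, float]]]

    def __post_init__(self):
        for clade, options in self.splits.items():
            total = sum(w for _, _, w in options)
            if abs(total - 1.0) > 1e-9:
                raise ReconciliationError(
                    f"conditional split frequencies for clade of size {len(clade)} "
                    f"sum to {total}")


def ccp_from_trees(trees: list[Tree]) -> CCPSet:
    """Clade and conditional split frequencies by counting over a rooted
    tree sample with identical leaf sets."""
    if not trees:
        raise ReconciliationError("need at least one tree")
    leaves = frozenset(trees[0].leaf_labels())
    clade_counts: dict[frozenset, int] = {}
    split_counts: dict[frozenset, dict] = {}
    for tree in trees:
        if frozenset(tree.leaf_labels()) != leaves:
            raise ReconciliationError("trees have inconsistent leaf sets")
        resolved = _resolve_multifurcations(tree)
        for node in resolved.postorder():
            clade = frozenset(l.label for l in _clade_leaves(node))
            clade_counts[clade] = clade_counts.get(clade, 0) + 1
            if node.children:
                a = frozenset(l.label for l in _clade_leaves(node.children[0]))
                b = clade - a
                key = (a, b) if sorted(a)[0] < sorted(b)[0] else (b, a)
                split_counts.setdefault(clade, {})
                split_counts[clade][key] = split_counts[clade].get(key, 0) + 1
    n = len(trees)
    clade_freq = {c: cnt / n for c, cnt in clade_counts.items()}
    splits = {}
    for clade, opts in split_counts.items():
        total = sum(opts.values())
        splits[clade] = [(a, b, cnt / total) for (a, b), cnt in sorted(
            opts.items(), key=lambda kv: (sorted(kv[0][0]), sorted(kv[0][1])))]
    return CCPSet(leaves, clade_freq, splits)


def ccp_from_family(family: GeneFamily) -> CCPSet:
    return ccp_from_trees([family.resolved_tree()])


# -- extinction probabilities ----------------------------------------------

def extinction_probs(stree: SpeciesTree, rates: DTLRates,
                     tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Fixed point of E_e = P_L + P_S*(E_f E_g | m_e) + P_D E_e^2 + P_T E_e Ebar."""
    p_s, p_d, p_t, p_l = rates.event_probs
    n = stree.n_branches
    E = np.zeros(n)
    leaf_term = np.array([
        stree.missing[e] if stree.children[e] is None else 0.0 for e in range(n)])
    internal = [e for e in range(n) if stree.children[e] is not None]
    for _ in range(max_iter):
        if n > 1:
            mean_other = (E.sum() - E) / (n - 1)
        else:
            mean_other = np.zeros(n)
        s_term = leaf_term.copy()
        for e in internal:
            f, g = stree.children[e]
            s_term[e] = E[f] * E[g]
        new = p_l + p_s * s_term + p_d * E ** 2 + p_t * E * mean_other
        if np.max(np.abs(new - E)) < tol:
            return new
        E = new
    raise ReconciliationError(
        f"extinction probabilities did not converge (residual {np.max(np.abs(new - E)):.3g})")


# -- the dynamic program ---------------------------------------------------

def _dtl_linear_operator(stree: SpeciesTree, rates: DTLRates,
                         E: np.ndarray) -> np.ndarray:
    """The matrix A = I - M of the self-referential (extinction-coupled)
    part of the undated DTL recursion, shared by the clade DP and the
    ghost-lineage expectations."""
    p_s, p_d, p_t, _ = rates.event_probs
    n = stree.n_branches
    mean_other_E = (E.sum() - E) / (n - 1) if n > 1 else np.zeros(n)
    M = np.zeros((n, n))
    for e in range(n):
        M[e, e] += 2.0 * p_d * E[e] + p_t * mean_other_E[e]
        if stree.children[e] is not None:
            f, g = stree.children[e]
            M[e, f] += p_s * E[g]
            M[e, g] += p_s * E[f]
        if n > 1:
            w = p_t * E[e] / (n - 1)
            M[e, :] += w
            M[e, e] -= w
    return np.eye(n) - M


def ghost_expectations(stree: SpeciesTree, rates: DTLRates,
                       E: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Expected per-branch copies and events contributed by an extinct
    ("ghost") gene lineage entering each branch.

    Row ``h`` of each matrix is the expectation, joint with eventual
    extinction, for a lineage entering branch ``h``; dividing by ``E_h``
    conditions on extinction.  These are the quantities a reconciliation
    of the observed gene tree cannot see: copies and events on lineages
    that left no sampled descendant, including truly present genes that
    escaped an incomplete genome assembly.
    """
    p_s, p_d, p_t, p_l = rates.event_probs
    n = stree.n_branches
    if E is None:
        E = extinction_probs(stree, rates)
    A = _dtl_linear_operator(stree, rates, E)
    B = {name: np.zeros((n, n)) for name in
         ("copies", "loss", "duplication", "transfer_in", "speciation")}
    for h in range(n):
        if stree.children[h] is None:
            B["copies"][h, h] = p_s * stree.missing[h]
        else:
            f, g = stree.children[h]
            B["copies"][h, h] = p_s * E[f] * E[g]
            B["speciation"][h, h] = p_s * E[f] * E[g]
        B["loss"][h, h] = p_l
        B["duplication"][h, h] = p_d * E[h] ** 2
        if n > 1:
            for k in range(n):
                if k != h:
                    B["transfer_in"][h, k] = p_t * E[h] * E[k] / (n - 1)
    Ainv = np.linalg.inv(A)
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, b in B.items():
            joint = Ainv @ b
            cond = np.where(E[:, None] > 0, joint / np.maximum(E[:, None], 1e-300), 0.0)
            out[name] = cond
    return out

class _FamilyDP:
    """Clade-by-branch survival probabilities for one family."""

    def __init__(self, family: GeneFamily, stree: SpeciesTree,
                 ccp: CCPSet | None = None):
        self.stree = stree
        self.ccp = ccp or ccp_from_family(family)
        for label in self.ccp.leaves:
            if species_of_leaf(label) not in stree.leaf_index:
                raise ReconciliationError(
                    f"gene leaf {label!r} maps to unknown species "
                    f"{species_of_leaf(label)!r}")
        self.clades = sorted(self.ccp.clade_freq, key=lambda c: (len(c), sorted(c)))

    def run(self, rates: DTLRates, E: np.ndarray | None = None):
        stree = self.stree
        n = stree.n_branches
        p_s, p_d, p_t, p_l = rates.event_probs
        if E is None:
            E = extinction_probs(stree, rates)
        A = _dtl_linear_operator(stree, rates, E)

        P: dict[frozenset, np.ndarray] = {}
        for clade in self.clades:
            b = np.zeros(n)
            if len(clade) == 1:
                label = next(iter(clade))
                leaf_branch = stree.leaf_index[species_of_leaf(label)]
                b[leaf_branch] += p_s * (1.0 - stree.missing[leaf_branch])
            else:
                for a_cl, b_cl, q in self.ccp.splits[clade]:
                    xa, xb = P[a_cl], P[b_cl]
                    mean_a = (xa.sum() - xa) / (n - 1) if n > 1 else np.zeros(n)
                    mean_b = (xb.sum() - xb) / (n - 1) if n > 1 else np.zeros(n)
                    term = 2.0 * p_d * xa * xb + p_t * (xa * mean_b + xb * mean_a)
                    for e in range(n):
                        if stree.children[e] is not None:
                            f, g = stree.children[e]
                            term[e] += p_s * (xa[f] * xb[g] + xa[g] * xb[f])
                    b += q * term
            P[clade] = np.linalg.solve(A, b)
        return P, E


def family_loglik(family: GeneFamily, stree: SpeciesTree, rates: DTLRates,
                  condition_on_observation: bool = True,
                  ccp: CCPSet | None = None) -> float:
    """Log-likelihood of a gene family under the undated DTL model with a
    uniform origination prior over species branches.

    Unrooted families are averaged over all rootings with a uniform prior.
    """
    if family.unrooted and family.tree is not None and ccp is None:
        liks = []
        for rooting in _all_rootings(family.tree):
            fam = GeneFamily(family.family_id, family.copy_counts, rooting)
            liks.append(np.exp(family_loglik(fam, stree, rates, False)))
        lik = float(np.mean(liks))
    else:
        dp = _FamilyDP(family, stree, ccp=ccp)
        P, E = dp.run(rates)
        lik = float(P[frozenset(dp.ccp.leaves)].mean())
    if condition_on_observation:
        E = extinction_probs(stree, rates)
        denom = 1.0 - float(E.mean())
        if denom <= 0:
            raise ReconciliationError("family observability is zero")
        lik /= denom
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


def _all_rootings(tree: Tree):
    """Every distinct rooting of an unrooted binary tree (one per edge of
    the unrooted topology), built from the adjacency graph."""
    base = _resolve_multifurcations(tree)
    adjacency: dict[int, list] = {}
    labels: dict[int, str | None] = {}
    nodes = base.postorder()
    for node in nodes:
        labels[id(node)] = node.label if node.is_leaf else None
        adjacency.setdefault(id(node), [])
        for child in node.children:
            adjacency[id(node)].append(id(child))
            adjacency.setdefault(id(child), []).append(id(node))
    # the arbitrary root of degree 2 is not a real unrooted vertex: fuse it
    root_id = id(base.root)
    if len(adjacency[root_id]) == 2:
        a, b = adjacency[root_id]
        adjacency[a] = [x for x in adjacency[a] if x != root_id] + [b]
        adjacency[b] = [x for x in adjacency[b] if x != root_id] + [a]
        del adjacency[root_id]

    def subtree(nid, parent) -> Node:
        node = Node(label=labels[nid])
        for nb in adjacency[nid]:
            if nb != parent:
                node.add_child(subtree(nb, nid))
        return node

    seen, out = set(), []
    edges = {tuple(sorted((u, v))) for u in adjacency for v in adjacency[u]}
    for u, v in sorted(edges):
        root = Node()
        root.add_child(subtree(u, v))
        root.add_child(subtree(v, u))
        rooted = Tree(root)
        key = _rooted_key(rooted)
        if key not in seen:
            seen.add(key)
            out.append(rooted)
    return out


def _rooted_key(tree: Tree) -> str:
    def key(node):
        if node.is_leaf:
            return node.label
        return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"
    return key(tree.root)


# -- rate estimation -------------------------------------------------------

def estimate_rates(families, stree: SpeciesTree,
                   init: tuple[float, float, float] = (0.01, 0.01, 0.01),
                   tol: float = 1e-3, condition_on_observation: bool = True,
                   max_rate: float = 10.0) -> DTLRates:
    """Pooled ML duplication/transfer/loss rates by Nelder–Mead in
    log-rate space."""
    if isinstance(families, GeneFamily):
        families = [families]
    dps = [_FamilyDP(f, stree) for f in families]

    def neg_loglik(log_rates: np.ndarray) -> float:
        r = np.exp(np.clip(log_rates, -20, np.log(max_rate)))
        rates = DTLRates(*r)
        try:
            E = extinction_probs(stree, rates)
        except ReconciliationError:
            return 1e12
        denom = 1.0 - float(E.mean())
        if denom <= 1e-12:
            return 1e12
        total = 0.0
        for dp in dps:
            P, _ = dp.run(rates, E)
            lik = float(P[frozenset(dp.ccp.leaves)].mean())
            if condition_on_observation:
                lik /= denom
            if lik <= 0:
                return 1e12
            total += np.log(lik)
        return -total

    x0 = np.log(np.asarray(init, dtype=float))
    res = minimize(neg_loglik, x0, method="Nelder-Mead",
                   options={"xatol": tol, "fatol": tol, "maxiter": 400})
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise ReconciliationError(f"rate optimisation failed: {res}")
    d, t, l = np.exp(np.clip(res.x, -20, np.log(max_rate)))
    return DTLRates(float(d), float(t), float(l))


# -- reconciliation sampling ----------------------------------------------

@dataclass
class ReconciliationSummary:
    family_id: str
    loglik: float
    expected: dict[str, np.ndarray]      # per-branch expected event counts + copies
    event_freq: dict[tuple, float]       # event key -> fraction of samples
    event_counts: dict[tuple, float]     # event key -> mean occurrences
    extinction: np.ndarray
    observability: float
    corrected_copies: np.ndarray
    samples: list | None = None
    theta_event: float = THETA_EVENT
    theta_present: float = THETA_PRESENT
    theta_maybe: float = THETA_MAYBE


def sample_reconciliations(family: GeneFamily, stree: SpeciesTree, rates: DTLRates,
                           n: int = 100, seed: int = 0,
                           keep_samples: bool = False) -> ReconciliationSummary:
    """Draw reconciliations by stochastic backtracking of the DP, in
    proportion to each scenario's contribution to the likelihood."""
    dp = _FamilyDP(family, stree)
    P, E = dp.run(rates)
    stv = stree
    nb = stv.n_branches
    p_s, p_d, p_t, p_l = rates.event_probs
    root_clade = frozenset(dp.ccp.leaves)
    root_weights = np.array([P[root_clade][e] for e in range(nb)])
    if root_weights.sum() <= 0:
        raise ReconciliationError("family has zero likelihood; cannot sample")
    rng = np.random.default_rng(seed)

    option_cache: dict[tuple, tuple] = {}

    def options(clade: frozenset, e: int):
        opts = []  # (weight, event record or None, recursion list)
        if len(clade) == 1:
            label = next(iter(clade))
            leaf_branch = stv.leaf_index[species_of_leaf(label)]
            if e == leaf_branch:
                opts.append((p_s * (1.0 - stv.missing[e]), ("C", e), []))
        if stv.children[e] is not None:
            f, g = stv.children[e]
            if len(clade) > 1:
                for a_cl, b_cl, q in dp.ccp.splits[clade]:
                    xa, xb = P[a_cl], P[b_cl]
                    opts.append((p_s * q * xa[f] * xb[g], ("S", e), [(a_cl, f), (b_cl, g)]))
                    opts.append((p_s * q * xa[g] * xb[f], ("S", e), [(a_cl, g), (b_cl, f)]))
            opts.append((p_s * P[clade][f] * E[g], ("SL", e, g), [(clade, f)]))
            opts.append((p_s * P[clade][g] * E[f], ("SL", e, f), [(clade, g)]))
        if len(clade) > 1:
            for a_cl, b_cl, q in dp.ccp.splits[clade]:
                xa, xb = P[a_cl], P[b_cl]
                opts.append((2.0 * p_d * q * xa[e] * xb[e], ("D", e), [(a_cl, e), (b_cl, e)]))
                for h in range(nb):
                    if h == e:
                        continue
                    w = p_t * q / (nb - 1)
                    opts.append((w * xa[e] * xb[h], ("T", e, h), [(a_cl, e), (b_cl, h)]))
                    opts.append((w * xb[e] * xa[h], ("T", e, h), [(b_cl, e), (a_cl, h)]))
        opts.append((2.0 * p_d * E[e] * P[clade][e], ("DL", e), [(clade, e)]))
        for h in range(nb):
            if h == e:
                continue
            w = p_t / (nb - 1)
            opts.append((w * E[h] * P[clade][e], ("TL", e, h, "recipient-lost"), [(clade, e)]))
            opts.append((w * E[e] * P[clade][h], ("TL", e, h, "donor-lost"), [(clade, h)]))
        return opts

    def cached_options(clade: frozenset, e: int):
        key = (clade, e)
        hit = option_cache.get(key)
        if hit is None:
            opts = options(clade, e)
            cum = np.cumsum([w for w, _, _ in opts])
            hit = (cum, [(rec, rc) for _, rec, rc in opts])
            option_cache[key] = hit
        return hit

    ghosts = ghost_expectations(stree, rates, E)
    sample_records = []
    copies = np.zeros((n, nb))
    ghost_copies = np.zeros((n, nb))
    sample_counters: list[Counter] = []
    counts = {"origination": np.zeros((n, nb)), "duplication": np.zeros((n, nb)),
              "transfer_in": np.zeros((n, nb)), "loss": np.zeros((n, nb)),
              "speciation": np.zeros((n, nb))}

    def consume_extinction(s: int, branch: int) -> None:
        # expected copies/events of the unsampled (ghost) sub-lineage
        ghost_copies[s] += ghosts["copies"][branch]
        for name in ("loss", "duplication", "transfer_in", "speciation"):
            counts[name][s] += ghosts[name][branch]

    for s in range(n):
        origin = int(rng.choice(nb, p=root_weights / root_weights.sum()))
        events = [("O", origin)]
        counts["origination"][s, origin] += 1
        stack = [(root_clade, origin)]
        guard = 0
        while stack:
            guard += 1
            if guard > 100_000:
                raise ReconciliationError("runaway backtracking; rates too high")
            clade, e = stack.pop()
            cum, recs = cached_options(clade, e)
            pick = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            pick = min(pick, len(recs) - 1)
            record, recurse = recs[pick]
            kind = record[0]
            if kind == "C":
                copies[s, e] += 1
                events.append(record)
            elif kind == "S":
                copies[s, e] += 1
                counts["speciation"][s, e] += 1
                events.append(record)
            elif kind == "SL":
                copies[s, e] += 1
                counts["speciation"][s, e] += 1
                consume_extinction(s, record[2])
                events.append(("S", e))
                events.append(("L", record[2]))
            elif kind == "D":
                counts["duplication"][s, e] += 1
                events.append(record)
            elif kind == "DL":
                counts["duplication"][s, e] += 1
                consume_extinction(s, e)
                events.append(("D", e))
                events.append(("L", e))
            elif kind == "T":
                counts["transfer_in"][s, record[2]] += 1
                events.append(record)
            elif kind == "TL":
                _, donor, recipient, which = record
                counts["transfer_in"][s, recipient] += 1
                lost = recipient if which == "recipient-lost" else donor
                consume_extinction(s, lost)
                events.append(("T", donor, recipient))
                events.append(("L", lost))
            stack.extend(recurse)
        sample_counters.append(Counter(events))
        if keep_samples:
            sample_records.append(events)

    all_keys = set().union(*sample_counters)
    event_freq = {k: sum(k in c for c in sample_counters) / n for k in all_keys}
    event_counts = {k: sum(c.get(k, 0) for c in sample_counters) / n for k in all_keys}

    expected = {name: arr.mean(axis=0) for name, arr in counts.items()}
    expected["copies"] = copies.mean(axis=0)
    observability = 1.0 - float(E.mean())
    if observability <= 0:
        raise ReconciliationError("family observability is zero")
    # extinction correction: add the expected copies of unsampled lineages
    corrected = expected["copies"] + ghost_copies.mean(axis=0)
    loglik = family_loglik(family, stree, rates)
    return ReconciliationSummary(
        family_id=family.family_id, loglik=loglik, expected=expected,
        event_freq=event_freq, event_counts=event_counts, extinction=E,
        observability=observability, corrected_copies=corrected,
        samples=sample_records if keep_samples else None)


def filter_events(frequencies: dict, theta_event: float = THETA_EVENT) -> dict:
    """Keep events whose sampled reconciliation frequency reaches the
    threshold (default 0.3)."""
    for k, f in frequencies.items():
        if not 0.0 <= f <= 1.0:
            raise ReconciliationError(f"event frequency {f} for {k} outside [0, 1]")
    return {k: f for k, f in frequencies.items() if f >= theta_event}


def ancestral_copy_numbers(summary: ReconciliationSummary) -> np.ndarray:
    """Per-branch corrected expected copy numbers: visible reconciliation
    copies plus the expected copies of ghost (extinct or unsampled)
    sub-lineages."""
    return summary.corrected_copies


def classify_presence(copy_number: float,
                      theta_present: float = THETA_PRESENT,
                      theta_maybe: float = THETA_MAYBE) -> str:
    """Presence call for an ancestral copy number: > 0.3 present,
    [0.1, 0.3] maybe_present, < 0.1 absent."""
    if copy_number < 0:
        raise ReconciliationError("copy number must be non-negative")
    if copy_number > theta_present:
        return "present"
    if copy_number >= theta_maybe:
        return "maybe_present"
    return "absent"


def singleton_origination(family: GeneFamily, stree: SpeciesTree) -> ReconciliationSummary:
    """A single-protein family is an origination at its leaf; no DP is run."""
    if family.size != 1:
        raise ReconciliationError("singleton handling requires a family of size 1")
    genome = next(g for g, c in family.copy_counts.items() if c == 1)
    if genome not in stree.leaf_index:
        raise ReconciliationError(f"singleton genome {genome!r} not in species tree")
    e = stree.leaf_index[genome]
    nb = stree.n_branches
    zeros = np.zeros(nb)
    copies = zeros.copy()
    copies[e] = 1.0
    orig = zeros.copy()
    orig[e] = 1.0
    expected = {"origination": orig, "duplication": zeros.copy(), "transfer_in": zeros.copy(),
                "loss": zeros.copy(), "speciation": zeros.copy(), "copies": copies}
    return ReconciliationSummary(
        family_id=family.family_id, loglik=0.0, expected=expected,
        event_freq={("O", e): 1.0, ("C", e): 1.0}, event_counts={("O", e): 1.0},
        extinction=np.zeros(nb), observability=1.0, corrected_copies=copies.copy())
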