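"""Ground-truthed simulators for every inference stage.

Three generators live here:

* Yule species trees;
* gene-family histories under the same discrete undated DTL process the
  reconciliation DP integrates over (event probabilities ``P_S, P_D, P_T,
  P_L``, uniform transfer recipients, per-leaf sampling failure ``m``), so
  simulator and likelihood are exact counterparts rather than
  approximations of each other;
* rate-heterogeneous alignments with branch-specific equilibrium
  frequencies, used to provoke and then cure compositional attraction.

:func:`artifact_scenario` bundles the last generator into a fixed
20-taxon benchmark: a fast-evolving query clade and a distant fast
outgroup lineage share a strong *within-recoding-bin* compositional bias,
so the convergent signal is invisible after four-state recoding — the
mechanism suspected whenever unrelated hyperthermophile lineages attract
each other in concatenated trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AA20, Alignment
from .models import SubstitutionModel, discrete_gamma_rates, poisson_model
from .recode import SR4_BINS
from .reconcile import DTLRates, SpeciesTree
from .trees import Node, Tree


class SimulationError(ValueError):
    pass


# -- species trees ---------------------------------------------------------

def simulate_species_tree(n_leaves: int, birth_rate: float = 1.0,
                          seed: int = 0) -> Tree:
    """Yule (pure-birth) tree with exponential branch lengths."""
    if n_leaves < 2:
        raise SimulationError("need at least two leaves")
    rng = np.random.default_rng(seed)
    tips = [Node(label=f"g{i+1}", length=0.0) for i in range(2)]
    root = Node(length=0.0)
    for t in tips:
        root.add_child(t)
    counter = 2
    while len(tips) < n_leaves:
        wait = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.length += wait
        split = tips[rng.integers(len(tips))]
        counter += 1
        a = Node(label=split.label, length=0.0)
        b = Node(label=f"g{counter}", length=0.0)
        split.label = None
        split.add_child(a)
        split.add_child(b)
        tips.remove(split)
        tips.extend([a, b])
    wait = rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.length += wait
    return Tree(root)


# -- gene families ---------------------------------------------------------

@dataclass
class FamilyHistory:
    events: list                      # (kind, branch[, recipient], order index)
    true_copies: np.ndarray           # per-branch completed lineage counts
    observed_counts: dict[str, int]   # genome -> observed copies
    gene_tree: Tree | None
    origin: int
    n_redraws: int = 0


def simulate_gene_family(stree: SpeciesTree, rates: DTLRates, seed: int = 0,
                         condition_on_observation: bool = True,
                         branch_rate_multipliers: dict[int, tuple[float, float, float]] | None = None,
                         origin: int | None = None,
                         max_events: int = 100_000) -> FamilyHistory:
    """One family history under the discrete undated DTL process.

    ``branch_rate_multipliers`` maps species-branch index to multipliers on
    (duplication, transfer, loss), letting clades evolve under shifted
    genome dynamics while the rest of the tree keeps the base rates.
    ``origin`` pins the originating species branch (e.g. the root branch
    for core families that predate the radiation); by default it is drawn
    uniformly, matching the reconciliation's origination prior.
    Conditioned simulation redraws histories with zero observed copies,
    mirroring the likelihood's conditioning on family observation.
    """
    rng = np.random.default_rng(seed)
    nb = stree.n_branches
    mult = branch_rate_multipliers or {}

    probs = np.zeros((nb, 4))
    for e in range(nb):
        md, mt, ml = mult.get(e, (1.0, 1.0, 1.0))
        d, t, l = rates.duplication * md, rates.transfer * mt, rates.loss * ml
        z = 1.0 + d + t + l
        probs[e] = (1.0 / z, d / z, t / z, l / z)

    n_redraws = 0
    while True:
        events: list = []
        true_copies = np.zeros(nb)
        observed: dict[str, int] = {}
        budget = [max_events]

        def evolve(e: int, depth: int = 0) -> Node | None:
            budget[0] -= 1
            if budget[0] <= 0 or depth > 400:
                raise SimulationError("runaway gene family (rates too high)")
            kind = rng.choice(4, p=probs[e])
            if kind == 3:  # loss
                events.append(("L", e, len(events)))
                return None
            if kind == 1:  # duplication
                events.append(("D", e, len(events)))
                left = evolve(e, depth + 1)
                right = evolve(e, depth + 1)
                return _join(left, right)
            if kind == 2:  # transfer
                h = int(rng.choice([x for x in range(nb) if x != e]))
                events.append(("T", e, h, len(events)))
                resident = evolve(e, depth + 1)
                moved = evolve(h, depth + 1)
                return _join(resident, moved)
            # speciation or leaf arrival
            if stree.children[e] is None:
                true_copies[e] += 1
                genome = stree.nodes[e].label
                if rng.random() < 1.0 - stree.missing[e]:
                    observed[genome] = observed.get(genome, 0) + 1
                    events.append(("C", e, len(events)))
                    return Node(label=f"{genome}|{observed[genome]}")
                events.append(("U", e, len(events)))
                return None
            true_copies[e] += 1
            events.append(("S", e, len(events)))
            f, g = stree.children[e]
            return _join(evolve(f, depth + 1), evolve(g, depth + 1))

        start = int(rng.integers(nb)) if origin is None else int(origin)
        events.append(("O", start, len(events)))
        root = evolve(start)
        if root is not None or not condition_on_observation:
            gene_tree = Tree(root) if root is not None else None
            if gene_tree is not None:
                for leaf in gene_tree.leaves():
                    if "|" in leaf.label and leaf.label.endswith("|1"):
                        genome = leaf.label.split("|")[0]
                        if observed[genome] == 1:
                            leaf.label = genome
            return FamilyHistory(events, true_copies, observed, gene_tree,
                                 start, n_redraws)
        n_redraws += 1
        if n_redraws > 1_000_000:
            raise SimulationError("family extinction rate too close to 1")


def _join(a: Node | None, b: Node | None) -> Node | None:
    if a is None:
        return b
    if b is None:
        return a
    node = Node()
    node.add_child(a)
    node.add_child(b)
    return node


# -- alignments ------------------------------------------------------------

@dataclass
class HeterogeneitySpec:
    """Among-site rate variation plus per-lineage composition overrides.

    ``frequency_overrides`` maps a clade identifier — a leaf label or a
    frozenset of leaf labels naming the stem branch of that clade — to an
    equilibrium-frequency vector; the override applies to the stem branch
    and everything below it.
    """

    alpha: float = 0.5
    n_rate_classes: int = 8
    frequency_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alpha <= 0:
            raise SimulationError("gamma shape must be positive")
        for key, pi in self.frequency_overrides.items():
            pi = np.asarray(pi, dtype=float)
            if not np.isclose(pi.sum(), 1.0):
                raise SimulationError(f"override for {key!r} does not sum to 1")


def simulate_alignment(tree: Tree, model: SubstitutionModel,
                       spec: HeterogeneitySpec, L: int, seed: int = 0,
                       symbols: str | None = None, alphabet: str | None = None):
    """Evolve an alignment down ``tree``; returns (Alignment, true site
    rates, true rate-class index per site).

    Branches under a frequency override use a rate matrix rebuilt around
    the overridden equilibrium with the same exchangeabilities.
    """
    if L < 1:
        raise SimulationError("need at least one column")
    rng = np.random.default_rng(seed)
    k = model.k
    if symbols is None:
        symbols = AA20 if k == 20 else "ACGT"[:k] if k <= 4 else None
    if symbols is None or len(symbols) != k:
        raise SimulationError("cannot infer symbols for this alphabet size")
    if alphabet is None:
        alphabet = "AA20" if k == 20 else "SR4" if symbols == "ACGT" else f"CUSTOM-{k}"

    rates = discrete_gamma_rates(spec.alpha, spec.n_rate_classes)
    classes = rng.integers(spec.n_rate_classes, size=L)
    site_rates = rates[classes]

    overrides = {}
    for key, pi in spec.frequency_overrides.items():
        ident = frozenset([key]) if isinstance(key, str) else frozenset(key)
        overrides[ident] = model.with_frequencies(np.asarray(pi, dtype=float))

    def branch_model(node: Node, inherited: SubstitutionModel) -> SubstitutionModel:
        ident = frozenset(l.label for l in _leaves_of(node))
        return overrides.get(ident, inherited)

    states: dict[int, np.ndarray] = {}
    models: dict[int, SubstitutionModel] = {}
    root = tree.root
    states[id(root)] = rng.choice(k, size=L, p=model.frequencies)
    models[id(root)] = model
    for node in tree.preorder():
        for child in node.children:
            m = branch_model(child, models[id(node)])
            models[id(child)] = m
            parent_states = states[id(node)]
            child_states = np.empty(L, dtype=np.int64)
            for c in range(spec.n_rate_classes):
                mask = classes == c
                if not mask.any():
                    continue
                P = m.transition(child.length, rates[c])
                cum = P.cumsum(axis=1)
                u = rng.random(mask.sum())
                rows = cum[parent_states[mask]]
                child_states[mask] = (u[:, None] > rows).sum(axis=1)
            states[id(child)] = child_states

    taxa = tree.leaf_labels()
    sym = np.array(list(symbols))
    data = np.stack([sym[states[id(tree.find_leaf(t))]] for t in taxa])
    aln = Alignment(list(taxa), data, alphabet, symbols)
    return aln, site_rates, classes


def _leaves_of(node: Node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


# -- the compositional-attraction benchmark --------------------------------

@dataclass
class ArtifactScenario:
    true_tree: Tree              # includes the query clade at its true position
    backbone: Tree               # query clade removed
    alignment: Alignment         # AA20, simulated under the true tree
    query_taxa: list[str]
    candidates: list[frozenset]  # candidate attachment edges on the backbone
    true_edge: frozenset         # sister edge of the query in the true tree
    attractor_edge: frozenset    # the convergent-composition outgroup edge
    clades: dict[str, list[str]]
    alpha: float
    site_rates: np.ndarray


def within_bin_biased_frequencies(concentration: float = 0.8) -> np.ndarray:
    """An AA composition shifted *within* each four-state recoding bin:
    one residue per bin carries ``concentration`` of the bin's mass, the
    rest share the remainder.  Bin-level totals stay uniform, so the bias
    vanishes upon four-state recoding.
    """
    favoured = {"A": "A", "C": "Y", "G": "K", "T": "I"}
    pi = np.zeros(20)
    for sym, residues in SR4_BINS.items():
        bin_mass = len(residues) / 20.0
        others = [r for r in residues if r != favoured[sym]]
        for r in residues:
            share = concentration if r == favoured[sym] else (1 - concentration) / len(others)
            pi[AA20.index(r)] = bin_mass * share
    return pi


_SCENARIO_NEWICK = (
    "((((((Hod1:0.08,Hod2:0.08):0.08,(Euk1:0.25,Euk2:0.25):1.6):0.05,"
    "(Heim1:0.12,Heim2:0.12):0.09):0.06,(Gerd1:0.1,Kari1:0.1):0.08):0.08,"
    "((Thor1:0.1,Thor2:0.1):0.07,(Loki1:0.12,Loki2:0.12):0.07):0.08):0.12,"
    "(((Kor1:0.3,Kor2:0.3):1.6,(Tack1:0.12,Tack2:0.12):0.09):0.07,"
    "((Eury1:0.12,Eury2:0.12):0.06,(Eury3:0.1,Eury4:0.1):0.06):0.07):0.12);"
)


def artifact_scenario(seed: int = 0, L: int = 1000, alpha: float = 0.5,
                      concentration: float = 0.9) -> ArtifactScenario:
    """The canned compositional long-branch-attraction benchmark.

    A 20-taxon tree: the query clade (Euk1, Euk2) is truly sister to a
    short-branch ingroup lineage (Hod1, Hod2), but the query stem and a
    distant outgroup clade (Kor1, Kor2) are both elongated and share the
    same within-bin composition override, emulating convergent amino-acid
    usage between unrelated fast-evolving lineages.
    """
    from .trees import parse_newick

    true_tree = parse_newick(_SCENARIO_NEWICK)
    query_taxa = ["Euk1", "Euk2"]
    pi_biased = within_bin_biased_frequencies(concentration)
    spec = HeterogeneitySpec(
        alpha=alpha,
        frequency_overrides={
            frozenset(query_taxa): pi_biased,
            frozenset(["Kor1", "Kor2"]): pi_biased,
        },
    )
    model = poisson_model(20)
    aln, site_rates, _ = simulate_alignment(true_tree, model, spec, L, seed=seed)
    backbone = true_tree.prune_taxa(query_taxa)
    true_edge = frozenset(["Hod1", "Hod2"])
    attractor_edge = frozenset(["Kor1", "Kor2"])
    candidates = [
        true_edge,
        attractor_edge,
        frozenset(["Heim1", "Heim2"]),
        frozenset(["Thor1", "Thor2"]),
        frozenset(["Hod1", "Hod2", "Heim1", "Heim2"]),
    ]
    clades = {
        "query": query_taxa,
        "attractor": ["Kor1", "Kor2"],
        "true_sister": ["Hod1", "Hod2"],
        "heim": ["Heim1", "Heim2"],
        "thor": ["Thor1", "Thor2"],
        "loki": ["Loki1", "Loki2"],
        "tack": ["Tack1", "Tack2"],
        "eury": ["Eury1", "Eury2", "Eury3", "Eury4"],
    }
    return ArtifactScenario(true_tree, backbone, aln, query_taxa, candidates,
                            true_edge, attractor_edge, clades, alpha, site_rates)
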