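import numpy as np
import pytest

from phylosieve.alignment import Alignment
from phylosieve.models import poisson_model
from phylosieve.reconcile import DTLRates, GeneFamily, SpeciesTree, estimate_rates
from phylosieve.synthetic import simulate_gene_family, simulate_species_tree
from phylosieve.trees import parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.3,B:0.9):0.2,(C:0.5,D:1.2):0.4);")


@pytest.fixture
def small_aa_alignment():
    rows = ["MKLVDE-AW?", "MKIVDEQAWC", "MRLVEEQGWC", "MRLV-EQGW?"]
    return Alignment(list("ABCD"), np.array([list(r) for r in rows]), "AA20")


@pytest.fixture
def toy_species_tree():
    tree = parse_newick("((A,B),C);")
    return SpeciesTree(tree, {"A": 0.1, "B": 0.0, "C": 0.2})


@pytest.fixture(scope="session")
def dtl_benchmark():
    """The shared DTL recovery benchmark: 200 families simulated on an
    8-leaf species tree with rates (0.1, 0.05, 0.3) and leaf missing
    fractions up to 0.3, plus the pooled rate fit."""
    tree = simulate_species_tree(8, seed=11)
    rng = np.random.default_rng(42)
    missing = {l: float(m) for l, m in zip(tree.leaf_labels(),
                                           rng.uniform(0, 0.3, 8))}
    stree = SpeciesTree(tree, missing)
    truth = DTLRates(0.1, 0.05, 0.3)
    histories, families = [], []
    for i in range(200):
        h = simulate_gene_family(stree, truth, seed=1000 + i)
        histories.append(h)
        families.append(GeneFamily.from_tree(f"fam{i}", h.gene_tree))
    estimate = estimate_rates(families, stree)
    return {
        "stree": stree,
        "truth": truth,
        "histories": histories,
        "families": families,
        "estimate": estimate,
    }


@pytest.fixture
def model4():
    return poisson_model(4)


@pytest.fixture
def model20():
    return poisson_model(20)
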