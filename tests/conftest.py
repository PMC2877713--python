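import numpy as np
import pytest

from grncompiler.graph_model import parse_network, gapgene_graph
from grncompiler.mechanisms import (
    two_regulator_graph,
    self_activation_network,
)
from grncompiler.regulation_compiler import Reaction, ReactionNetwork, compile_reactions
from grncompiler.mass_action import build_odes, conservation_laws, reduce_by_conservation


@pytest.fixture
def fig1_graph():
    return gapgene_graph()


@pytest.fixture
def two_reg_graph():
    return two_regulator_graph()


def make_self_activation_reduced(C, k_bind=1.0, k_unbind=1.0,
                                 k_production=1.0, k_degradation=0.1):
    """Conservation-reduced self-activation system at gene total C."""
    net = self_activation_network(k_bind, k_unbind, k_production, k_degradation)
    net.initial_conditions.update({"A_a0": C, "A_a1": 0.0, "A": 0.0})
    odesys = build_odes(net)
    laws = conservation_laws(odesys)
    return reduce_by_conservation(odesys, laws, ["A_a0"])


def random_reaction_network(rng, n_species=4, n_reactions=5):
    """A random mass-action network of at-most-bimolecular reactions."""
    species = [f"S{i}" for i in range(n_species)]
    reactions = []
    params = {}
    for j in range(n_reactions):
        n_react = int(rng.integers(0, 3))
        n_prod = int(rng.integers(0 if n_react else 1, 3))
        reactants = {}
        for s in rng.choice(species, size=n_react, replace=True):
            reactants[s] = reactants.get(s, 0) + 1
        products = {}
        for s in rng.choice(species, size=n_prod, replace=True):
            products[s] = products.get(s, 0) + 1
        k = float(10 ** rng.uniform(-1, 0.5))
        name = f"k{j}"
        params[name] = k
        reactions.append(Reaction(reactants, products, name, k))
    ics = {s: float(rng.uniform(0.1, 2.0)) for s in species}
    net = ReactionNetwork(species, reactions, params, set(), ics)
    net.validate()
    return net


def random_compiled_network(rng):
    """Compile a random small regulatory double graph with random rates."""
    n = int(rng.integers(2, 5))
    vertices = [f"G{i}" for i in range(n)]
    acts, reps = [], []
    for s in vertices:
        for t in vertices:
            u = rng.random()
            if u < 0.25:
                acts.append((s, t))
            elif u < 0.4:
                reps.append((s, t))
    graph = parse_network(acts, reps, extra_vertices=vertices)
    semantics = "per_site" if rng.random() < 0.5 else "one_site"
    net = compile_reactions(graph, semantics)
    for name in net.parameters:
        net.parameters[name] = float(10 ** rng.uniform(-1, 0.5))
    net = net.with_parameters(net.parameters)
    for s in net.species:
        net.initial_conditions[s] = float(rng.uniform(0.05, 1.5))
    return net
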