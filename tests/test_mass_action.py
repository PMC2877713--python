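import numpy as np
import pytest
import sympy as sp

from grncompiler.mass_action import (
    ConfigurationError,
    EliminationError,
    build_odes,
    conservation_laws,
    reduce_by_conservation,
)
from grncompiler.mechanisms import (
    full_production_network,
    reduced_production_network,
    self_activation_network,
)
from grncompiler.regulation_compiler import Reaction, ReactionNetwork, compile_reactions
from grncompiler.dynamics import integrate

from conftest import random_compiled_network, random_reaction_network


def brute_force_rhs(network, concentrations):
    """Independent flux accumulator: loop reactions, accumulate
    (products - reactants) * k * prod(conc^stoich) per species."""
    out = {s: 0.0 for s in network.species}
    for r in network.reactions:
        flux = r.rate_value
        for s, a in r.reactants.items():
            flux *= concentrations[s] ** a
        for s, a in r.reactants.items():
            out[s] -= a * flux
        for s, b in r.products.items():
            out[s] += b * flux
    return out


class TestBuildOdes:
    def test_reduced_mechanism_equations(self):
        """G -> G + P, P -> 0 gives dG/dt = 0, dP/dt = k1 G - k2 P."""
        ode = build_odes(reduced_production_network(1.3, 0.4, gene0=2.0))
        x = np.array([2.0, 0.7])      # (G, P)
        rhs = ode.rhs(x)
        iG, iP = ode.species_index("G"), ode.species_index("P")
        assert rhs[iG] == pytest.approx(0.0, abs=1e-15)
        assert rhs[iP] == pytest.approx(1.3 * 2.0 - 0.4 * 0.7)

    def test_two_regulator_per_site_field(self, two_reg_graph):
        """Compiled rate equations balance binding, unbinding, production
        and degradation with the regulators folded in as constants."""
        net = compile_reactions(two_reg_graph, "per_site")
        net.initial_conditions.update({"A": 2.0, "R": 3.0})
        ode = build_odes(net)
        assert set(ode.constant_species) == {"A", "R"}
        assert ode.n_state == 5
        x = np.linspace(0.2, 1.0, 5)
        rhs = ode.rhs(x)
        conc = {s: x[ode.species_index(s)] for s in ode.state_species}
        conc.update({"A": 2.0, "R": 3.0})
        brute = brute_force_rhs(net, conc)
        for s in ode.state_species:
            assert rhs[ode.species_index(s)] == pytest.approx(brute[s])

    def test_empty_reaction_list(self):
        net = ReactionNetwork(["X"], [], {}, set(), {"X": 1.0})
        ode = build_odes(net)
        assert ode.rhs(np.array([3.0])) == pytest.approx([0.0])

    @pytest.mark.parametrize("trial", range(10))
    def test_random_networks_match_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        net = random_reaction_network(rng)
        ode = build_odes(net)
        x = rng.uniform(0.1, 2.0, ode.n_state)
        conc = {s: x[ode.species_index(s)] for s in ode.state_species}
        brute = brute_force_rhs(net, conc)
        rhs = ode.rhs(x)
        for s in ode.state_species:
            assert rhs[ode.species_index(s)] == pytest.approx(brute[s], rel=1e-12)

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        net = random_reaction_network(rng)
        ode = build_odes(net)
        x = rng.uniform(0.2, 1.5, ode.n_state)
        J = ode.jacobian(x)
        eps = 1e-7
        for i in range(ode.n_state):
            dx = np.zeros(ode.n_state)
            dx[i] = eps
            fd = (ode.rhs(x + dx) - ode.rhs(x - dx)) / (2 * eps)
            assert J[:, i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_constant_without_value_raises(self, two_reg_graph):
        net = compile_reactions(two_reg_graph, "per_site")
        with pytest.raises(ConfigurationError):
            build_odes(net)

    def test_catalyst_species_have_zero_rhs(self):
        ode = build_odes(full_production_network())
        x = np.random.default_rng(0).uniform(0.1, 2.0, ode.n_state)
        rhs = ode.rhs(x)
        for cat in ("G", "Pol"):
            assert rhs[ode.species_index(cat)] == 0.0


class TestConservationLaws:
    def test_two_regulator_operon_total(self, two_reg_graph):
        net = compile_reactions(two_reg_graph, "per_site")
        net.initial_conditions.update({"A": 1.0, "R": 1.0, "B_a0_r0": 0.7})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        assert len(laws) == 1
        law = laws[0]
        nonzero = {s for s, c in zip(law.species, law.coefficients) if c}
        assert nonzero == {"B_a0_r0", "B_a0_r1", "B_a1_r0", "B_a1_r1"}
        assert set(law.coefficients) <= {0, 1}
        assert law.constant == pytest.approx(0.7)

    def test_one_site_operon_total(self, two_reg_graph):
        net = compile_reactions(two_reg_graph, "one_site")
        net.initial_conditions.update({"A": 1.0, "R": 1.0})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        assert len(laws) == 1
        nonzero = {s for s, c in zip(laws[0].species, laws[0].coefficients) if c}
        assert nonzero == {"B_free", "B_A", "B_R"}

    def test_pure_decay_has_no_law(self):
        net = ReactionNetwork(["X"], [Reaction({"X": 1}, {}, "k", 1.0)],
                              {"k": 1.0}, set(), {"X": 1.0})
        assert conservation_laws(build_odes(net)) == []

    @pytest.mark.parametrize("trial", range(20))
    def test_random_networks_annihilate_gamma_exactly(self, trial):
        """Every returned vector is an exact integer left-null vector, and
        the basis size equals n_species - rank(Gamma) by an SVD oracle."""
        rng = np.random.default_rng(300 + trial)
        net = random_compiled_network(rng)
        ode = build_odes(net)
        laws = conservation_laws(ode)
        for law in laws:
            res = np.array(law.coefficients, dtype=object) @ ode.stoich_matrix
            assert all(v == 0 for v in res)
            ints = [c for c in law.coefficients if c]
            assert np.gcd.reduce(np.abs(ints)) == 1
            assert ints[0] > 0
        rank = np.linalg.matrix_rank(ode.stoich_matrix.astype(float))
        assert len(laws) == ode.n_state - rank

    def test_laws_constant_along_trajectory(self):
        net = self_activation_network()
        net.initial_conditions.update({"A_a0": 0.6, "A_a1": 0.1, "A": 0.3})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        assert len(laws) == 1
        traj = integrate(ode, ode.initial_state(), 50.0)
        vals = traj.states @ np.array(laws[0].coefficients)
        assert np.max(np.abs(vals - vals[0])) / vals[0] < 1e-6


class TestReduceByConservation:
    def test_self_activation_reduction_dimension(self):
        net = self_activation_network()
        net.initial_conditions.update({"A_a0": 0.5})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        red = reduce_by_conservation(ode, laws, ["A_a0"])
        assert red.n_state == 2
        assert set(red.state_species) == {"A", "A_a1"}
        # symbolic check: substituting A_a0 = C - A_a1 throughout
        syms, exprs = red.to_sympy()
        b = sp.Symbol("A_a1")
        A = sp.Symbol("A")
        kb, ku, kp, kd = [sp.Symbol(n, positive=True)
                          for n in ("kb_A_A", "ku_A_A", "kp_A_a1", "kd_A")]
        expected = {
            "A_a1": kb * A * (sp.Rational(1, 2) - b) - ku * b,
            "A": -kb * A * (sp.Rational(1, 2) - b) + ku * b + kp * b - kd * A,
        }
        for s, e in zip(red.state_species, exprs):
            assert sp.simplify(e - expected[s]) == 0

    def test_reduction_preserves_trajectories(self):
        net = self_activation_network(1.0, 0.8, 2.0, 0.3)
        net.initial_conditions.update({"A_a0": 0.4, "A_a1": 0.1, "A": 0.2})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        red = reduce_by_conservation(ode, laws, ["A_a0"])
        t_eval = np.linspace(0, 20, 50)
        full = integrate(ode, ode.initial_state(), 20.0, t_eval=t_eval)
        y0 = [full.states[0][ode.species_index(s)] for s in red.state_species]
        reduced = integrate(red, y0, 20.0, t_eval=t_eval)
        for s in red.state_species:
            assert np.max(np.abs(full[s] - reduced[s])) < 1e-7
        # eliminated species reconstructs the full trajectory
        recon = np.array([red.full_state(y)[ode.species_index("A_a0")]
                          for y in reduced.states])
        assert np.max(np.abs(recon - full["A_a0"])) < 1e-7

    def test_zero_constant_pins_species_at_zero(self):
        net = self_activation_network()
        net.initial_conditions.update({"A_a0": 0.0, "A_a1": 0.0})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        red = reduce_by_conservation(ode, laws, ["A_a0"])
        y = np.array([0.5, 0.0])  # A = 0.5, A_a1 = 0
        full = red.full_state(y)
        assert full[ode.species_index("A_a0")] == 0.0

    def test_zero_coefficient_elimination_error(self):
        net = self_activation_network()
        net.initial_conditions.update({"A_a0": 0.5})
        ode = build_odes(net)
        laws = conservation_laws(ode)
        with pytest.raises(EliminationError):
            reduce_by_conservation(ode, laws, ["A"])   # A not in the gene total


def test_closed_form_full_mechanism_shape():
    """The explicit transcription/translation chain relaxes to a steady
    state proportional to the gene concentration."""
    for g0 in (0.5, 1.0, 2.0):
        net = full_production_network(gene0=g0)
        ode = build_odes(net)
        traj = integrate(ode, ode.initial_state(), 200.0)
        p_ss = traj["P"][-1]
        # P* = k_tc k_tl G Pol / (k_dr k_dp)
        assert p_ss == pytest.approx(1.0 * 1.0 * g0 * 1.0 / (0.5 * 0.2), rel=1e-6)


def test_ode_pretty_printer_and_json(two_reg_graph):
    net = compile_reactions(two_reg_graph, "one_site")
    net.initial_conditions.update({"A": 1.0, "R": 1.0})
    ode = build_odes(net)
    text = ode.format()
    assert "dB/dt" in text and "kd_B" in text
    import json
    payload = json.loads(ode.to_json())
    assert payload["state_species"] == ode.state_species
    assert len(payload["fluxes"]) == len(ode.fluxes)
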