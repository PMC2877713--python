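import numpy as np
import pytest
import sympy as sp

from grncompiler.mechanisms import patterning_motif_graph
from grncompiler.regulation_compiler import compile_reactions
from grncompiler.spatial import (
    NonlinearSystemError,
    SpatialField,
    SpatialProfile,
    linear_steady_state,
    simulate_field,
)


def motif_inputs(n=60, r_amp=3.0):
    x = np.linspace(0, 1, n)
    return SpatialField({
        "A": SpatialProfile(x, np.full(n, 1.0)),
        "R1": SpatialProfile(x, r_amp * np.exp(-((x - 0.3) ** 2) / (2 * 0.07**2))),
        "R2": SpatialProfile(x, r_amp * np.exp(-((x - 0.7) ** 2) / (2 * 0.07**2))),
    })


def interior_maxima(values):
    return [
        i for i in range(1, len(values) - 1)
        if values[i] >= values[i - 1] and values[i] > values[i + 1]
    ]


class TestSpatialProfile:
    def test_validation(self):
        with pytest.raises(ValueError):
            SpatialProfile(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            SpatialProfile(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            SpatialProfile(np.array([0.0, 1.0]), np.array([1.0]))

    def test_csv_roundtrip(self, tmp_path):
        p = SpatialProfile(np.array([0.0, 0.5, 1.0]), np.array([1.0, 2.0, 0.5]),
                           np.array([0.1, 0.2, 0.1]))
        path = tmp_path / "prof.csv"
        p.to_csv(path)
        back = SpatialProfile.from_csv(path)
        assert np.allclose(back.positions, p.positions)
        assert np.allclose(back.values, p.values)
        assert np.allclose(back.sd, p.sd)

    def test_field_requires_shared_grid(self):
        a = SpatialProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        b = SpatialProfile(np.array([0.0, 0.5]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            SpatialField({"A": a, "B": b})

    def test_wide_csv_roundtrip(self, tmp_path):
        f = motif_inputs(10)
        path = tmp_path / "field.csv"
        f.to_wide_csv(path)
        back = SpatialField.from_wide_csv(path)
        assert set(back) == set(f)
        for k in f:
            assert np.allclose(back[k].values, f[k].values)


class TestSimulateField:
    def test_spiky_interior_maximum_one_site(self):
        """Flanking repressor bumps around a flat activator carve a single
        interior expression peak between them."""
        net = compile_reactions(patterning_motif_graph(), "one_site")
        out = simulate_field(net, motif_inputs(), {"C_free": 1.0}, t_final=150.0,
                             n_steps=3000)
        c = out["C"].values
        peaks = interior_maxima(c)
        assert len(peaks) == 1
        assert 0.3 < out["C"].positions[peaks[0]] < 0.7

    def test_per_site_variant_same_qualitative_result(self):
        net = compile_reactions(
            patterning_motif_graph(), "per_site",
            rate_values={"kp_C_a1r10": 0.02, "kp_C_a1r01": 0.02,
                         "kp_C_a1r11": 0.01},
        )
        out = simulate_field(net, motif_inputs(), {"C_a0_r00": 1.0},
                             t_final=150.0, n_steps=3000)
        peaks = interior_maxima(out["C"].values)
        assert len(peaks) == 1
        assert 0.3 < out["C"].positions[peaks[0]] < 0.7

    def test_flat_inputs_flat_output(self):
        n = 20
        x = np.linspace(0, 1, n)
        flat = SpatialField({
            s: SpatialProfile(x, np.full(n, v))
            for s, v in (("A", 1.0), ("R1", 0.5), ("R2", 0.5))
        })
        net = compile_reactions(patterning_motif_graph(), "one_site")
        out = simulate_field(net, flat, {"C_free": 1.0}, t_final=50.0)
        for s in out:
            assert np.ptp(out[s].values) < 1e-9

    def test_locality_under_position_permutation(self):
        """No coupling between positions: permuting the input columns
        permutes the outputs identically."""
        net = compile_reactions(patterning_motif_graph(), "one_site")
        inputs = motif_inputs(16)
        out = simulate_field(net, inputs, {"C_free": 1.0}, t_final=30.0)
        x = inputs.positions
        perm_vals = {s: inputs[s].values[::-1].copy() for s in inputs}
        perm = SpatialField({s: SpatialProfile(x, v) for s, v in perm_vals.items()})
        out_perm = simulate_field(net, perm, {"C_free": 1.0}, t_final=30.0)
        assert np.allclose(out_perm["C"].values, out["C"].values[::-1],
                           rtol=1e-10, atol=1e-12)

    def test_gene_total_conserved_at_every_position(self):
        net = compile_reactions(patterning_motif_graph(), "one_site")
        out = simulate_field(net, motif_inputs(20), {"C_free": 0.8}, t_final=20.0)
        total = sum(out[s].values for s in ("C_free", "C_A", "C_R1", "C_R2"))
        assert np.allclose(total, 0.8, rtol=1e-7)

    def test_missing_input_profile_raises(self):
        net = compile_reactions(patterning_motif_graph(), "one_site")
        inputs = motif_inputs(10)
        del inputs["R2"]
        with pytest.raises(KeyError):
            simulate_field(net, inputs, {"C_free": 1.0}, t_final=1.0)


class TestLinearSteadyState:
    def test_matches_long_time_integration(self):
        net = compile_reactions(patterning_motif_graph(), "one_site")
        inputs = motif_inputs()
        lin = linear_steady_state(net, inputs, {"C_free": 1.0})
        sim = simulate_field(net, inputs, {"C_free": 1.0}, t_final=200.0,
                             n_steps=4000)
        c_lin, c_sim = lin["C"].values, sim["C"].values
        rel = np.abs(c_sim - c_lin) / np.abs(c_lin)
        assert rel.max() < 1e-8

    def test_closed_form_competitive_site(self):
        """The symbolic steady state of the competitive-site motif:
        C* = (p/d) * Ctot * (a A / a') / (1 + aA/a' + r1 R1/r1' + r2 R2/r2')."""
        net = compile_reactions(patterning_motif_graph(), "one_site")
        inputs = motif_inputs(12)
        lin = linear_steady_state(net, inputs, {"C_free": 1.0})
        A = inputs["A"].values
        R1, R2 = inputs["R1"].values, inputs["R2"].values
        p = net.parameters["kp_C_A"]
        d = net.parameters["kd_C"]
        occ_A = net.parameters["kb_C_A"] / net.parameters["ku_C_A"] * A
        occ1 = net.parameters["kb_C_R1"] / net.parameters["ku_C_R1"] * R1
        occ2 = net.parameters["kb_C_R2"] / net.parameters["ku_C_R2"] * R2
        expected = (p / d) * 1.0 * occ_A / (1.0 + occ_A + occ1 + occ2)
        assert np.allclose(lin["C"].values, expected, rtol=1e-12)

    def test_symbolic_rederivation(self):
        """Independent sympy solve of the affine steady state equals the
        numeric linear solver at one position."""
        net = compile_reactions(patterning_motif_graph(), "one_site")
        a, r1, r2 = 1.0, 2.0, 0.4
        x = np.array([0.0, 1.0])
        inputs = SpatialField({
            "A": SpatialProfile(x, np.full(2, a)),
            "R1": SpatialProfile(x, np.full(2, r1)),
            "R2": SpatialProfile(x, np.full(2, r2)),
        })
        lin = linear_steady_state(net, inputs, {"C_free": 1.0})
        syms = {s: sp.Symbol(s) for s in
                ("C_free", "C_A", "C_R1", "C_R2", "C")}
        k = {n: sp.Rational(v) for n, v in net.parameters.items()}
        eqs = [
            sp.Eq(k["kb_C_A"] * a * syms["C_free"], k["ku_C_A"] * syms["C_A"]),
            sp.Eq(k["kb_C_R1"] * r1 * syms["C_free"], k["ku_C_R1"] * syms["C_R1"]),
            sp.Eq(k["kb_C_R2"] * r2 * syms["C_free"], k["ku_C_R2"] * syms["C_R2"]),
            sp.Eq(k["kp_C_A"] * syms["C_A"], k["kd_C"] * syms["C"]),
            sp.Eq(sum(syms[s] for s in ("C_free", "C_A", "C_R1", "C_R2")), 1),
        ]
        sol = sp.solve(eqs, list(syms.values()), dict=True)[0]
        for s in syms:
            assert lin[s].values[0] == pytest.approx(float(sol[syms[s]]),
                                                     rel=1e-10)

    def test_zero_repressors_reduces_to_activated_gene(self):
        net = compile_reactions(patterning_motif_graph(), "one_site")
        n = 8
        x = np.linspace(0, 1, n)
        inputs = SpatialField({
            "A": SpatialProfile(x, np.full(n, 1.0)),
            "R1": SpatialProfile(x, np.zeros(n)),
            "R2": SpatialProfile(x, np.zeros(n)),
        })
        lin = linear_steady_state(net, inputs, {"C_free": 1.0})
        assert np.ptp(lin["C"].values) < 1e-12
        p, d = net.parameters["kp_C_A"], net.parameters["kd_C"]
        occ = net.parameters["kb_C_A"] / net.parameters["ku_C_A"]
        assert lin["C"].values[0] == pytest.approx(p / d * occ / (1 + occ))

    def test_monotone_repression(self):
        net = compile_reactions(patterning_motif_graph(), "one_site")
        inputs = motif_inputs(25, r_amp=2.0)
        doubled = SpatialField({
            "A": inputs["A"],
            "R1": SpatialProfile(inputs.positions, 2 * inputs["R1"].values),
            "R2": SpatialProfile(inputs.positions, 2 * inputs["R2"].values),
        })
        base = linear_steady_state(net, inputs, {"C_free": 1.0})["C"].values
        more = linear_steady_state(net, doubled, {"C_free": 1.0})["C"].values
        assert np.all(more <= base + 1e-12)

    def test_nonlinear_network_rejected(self):
        """The self-activating gene multiplies two state variables, so the
        closed-form linear solver must refuse it."""
        from grncompiler.mechanisms import self_activation_graph
        net = compile_reactions(self_activation_graph(), "per_site")
        x = np.array([0.0, 1.0])
        dummy = SpatialField({"unused": SpatialProfile(x, np.zeros(2))})
        with pytest.raises(NonlinearSystemError):
            linear_steady_state(net, dummy, {"A_a0": 1.0})
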