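"""Canonical small mechanisms and their closed-form solutions.

These are the textbook fixtures of the framework: the full transcription +
translation mechanism, its reduced (lumped) form, the two-regulator example
gene, the self-activating gene whose conserved total drives the threshold
bifurcation, and the one-activator/two-repressor patterning motif.  The
linear mechanisms carry exact solutions used as integration oracles.
"""

from __future__ import annotations

import numpy as np

from .graph_model import DoubleGraph, parse_network
from .regulation_compiler import Reaction, ReactionNetwork, compile_reactions

__all__ = [
    "full_production_network",
    "reduced_production_network",
    "reduced_production_solution",
    "two_regulator_graph",
    "self_activation_graph",
    "self_activation_network",
    "patterning_motif_graph",
    "self_activation_threshold",
]


def full_production_network(
    k_transcribe: float = 1.0,
    k_translate: float = 1.0,
    k_mrna_decay: float = 0.5,
    k_protein_decay: float = 0.2,
    gene0: float = 1.0,
    polymerase0: float = 1.0,
) -> ReactionNetwork:
    """Transcription and translation as explicit catalytic steps.

    G + Pol -> G + Pol + R;  R -> R + P;  R -> 0;  P -> 0.
    Gene and polymerase are perfect catalysts; mRNA R turns over.  The
    system is linear, with steady state P* = k1*k2*G*Pol/(k3*k4),
    proportional to the gene concentration.
    """
    reactions = [
        Reaction({"G": 1, "Pol": 1}, {"G": 1, "Pol": 1, "R": 1}, "k_tc", k_transcribe),
        Reaction({"R": 1}, {"R": 1, "P": 1}, "k_tl", k_translate),
        Reaction({"R": 1}, {}, "k_dr", k_mrna_decay),
        Reaction({"P": 1}, {}, "k_dp", k_protein_decay),
    ]
    net = ReactionNetwork(
        ["G", "Pol", "R", "P"],
        reactions,
        {"k_tc": k_transcribe, "k_tl": k_translate, "k_dr": k_mrna_decay,
         "k_dp": k_protein_decay},
        constant_species=set(),
        initial_conditions={"G": gene0, "Pol": polymerase0, "R": 0.0, "P": 0.0},
    )
    net.validate()
    return net


def reduced_production_network(
    k_production: float = 1.0,
    k_degradation: float = 0.2,
    gene0: float = 1.0,
    protein0: float = 0.0,
) -> ReactionNetwork:
    """The lumped protein-production mechanism: G -> G + P;  P -> 0.

    Keeps the catalytic role of the gene while hiding polymerase and mRNA.
    dG/dt = 0 and dP/dt = k1*G - k2*P, with exact solution
    ``reduced_production_solution``.
    """
    reactions = [
        Reaction({"G": 1}, {"G": 1, "P": 1}, "k1", k_production),
        Reaction({"P": 1}, {}, "k2", k_degradation),
    ]
    net = ReactionNetwork(
        ["G", "P"],
        reactions,
        {"k1": k_production, "k2": k_degradation},
        constant_species=set(),
        initial_conditions={"G": gene0, "P": protein0},
    )
    net.validate()
    return net


def reduced_production_solution(
    t: np.ndarray,
    k_production: float,
    k_degradation: float,
    gene0: float,
    protein0: float = 0.0,
) -> np.ndarray:
    """Exact protein trajectory of the lumped mechanism.

    P(t) = (k1*G0/k2) (1 - exp(-k2 t)) + P0 exp(-k2 t): the steady state
    k1*G0/k2 is proportional to the (conserved) gene concentration.
    """
    t = np.asarray(t, dtype=float)
    pss = k_production * gene0 / k_degradation
    return pss + (protein0 - pss) * np.exp(-k_degradation * t)


def two_regulator_graph() -> DoubleGraph:
    """One gene B with activator A and repressor R (both constant inputs)."""
    return parse_network(
        [("A", "B")],
        [("R", "B")],
        annotations={"A": {"constant_input": True}, "R": {"constant_input": True}},
    )


def self_activation_graph() -> DoubleGraph:
    """A protein that activates its own gene: the minimal threshold motif."""
    return parse_network([("A", "A")], [])


def self_activation_network(
    k_bind: float = 1.0,
    k_unbind: float = 1.0,
    k_production: float = 1.0,
    k_degradation: float = 0.1,
) -> ReactionNetwork:
    """Compiled self-activation motif with named rates.

    Species: free operon A_a0, bound operon A_a1, protein A.  Reactions:
    A + A_a0 <-> A_a1;  A_a1 -> A_a1 + A;  A -> 0.  The operon total
    C = A_a0 + A_a1 is conserved and acts as the bifurcation parameter,
    with threshold C* = k_unbind*k_degradation/(k_bind*k_production)
    (see ``self_activation_threshold``).
    """
    return compile_reactions(
        self_activation_graph(),
        semantics="per_site",
        rate_values={
            "kb_A_A": k_bind,
            "ku_A_A": k_unbind,
            "kp_A_a1": k_production,
            "kd_A": k_degradation,
        },
    )


def self_activation_threshold(
    k_bind: float, k_unbind: float, k_production: float, k_degradation: float
) -> float:
    """Critical conserved gene total of the self-activation motif.

    On the reduced 2-variable system (operon-bound fraction b, protein A)

        db/dt = k_b A (C - b) - k_u b
        dA/dt = -k_b A (C - b) + (k_u + k_p) b - k_d A

    the zero branch (b, A) = (0, 0) has Jacobian determinant
    k_u*k_d - k_b*k_p*C, which changes sign at

        C* = (k_u * k_d) / (k_b * k_p).

    Below C* the quiescent state is stable; above it the positive branch
    b* = C - C*, A* = k_p b*/k_d takes over (transcritical exchange).
    """
    return (k_unbind * k_degradation) / (k_bind * k_production)


def patterning_motif_graph() -> DoubleGraph:
    """Protein C with one activator A and two repressors R1, R2.

    With A, R1, R2 constant in space-dependent profiles and competitive
    (one-site) regulation, the kinetics are linear and the steady state of
    C is available in closed form; flanking repressor profiles carve a
    spiky interior expression domain.
    """
    return parse_network(
        [("A", "C")],
        [("R1", "C"), ("R2", "C")],
        annotations={
            "A": {"constant_input": True},
            "R1": {"constant_input": True},
            "R2": {"constant_input": True},
        },
    )
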