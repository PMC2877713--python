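"""Compile a regulatory double graph into a mass-action reaction network.

The operon picture: every gene carries transcription-factor binding sites,
and regulation acts only through site occupancy.  Two semantics are
implemented:

``per_site``
    Each incoming regulation edge contributes its own binding site, so a
    gene with *a* activators and *r* repressors has ``2**(a+r)`` operon
    occupancy states.  Transcription fires from every state with at least
    one activator bound, with a separate production rate per occupancy
    pattern.

``one_site``
    All regulators compete for a single site: the operon has the free state
    plus one singly-bound state per regulator (``a+r+1`` states), and only
    activator-bound states produce.

Proteins always degrade; gene (operon) species are perfect catalysts that
never degrade, which is what generates a gene-total conservation law per
gene.  A regulator bound to DNA is sequestered: it does not degrade while
bound, keeping the gene totals exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .graph_model import DoubleGraph, regulators_of

__all__ = [
    "OperonState",
    "Reaction",
    "ReactionNetwork",
    "Semantics",
    "enumerate_operon_states",
    "compile_reactions",
    "DEFAULT_RATES",
]

Semantics = Literal["per_site", "one_site"]

#: Default rate constants used when the caller provides none (arbitrary
#: units: binding per-concentration-per-time, the rest per-time).
DEFAULT_RATES = {
    "bind": 1.0,
    "unbind": 1.0,
    "production": 1.0,
    "degradation": 0.1,
}


@dataclass(frozen=True)
class OperonState:
    """One occupancy pattern of a gene's binding sites.

    ``activator_mask`` / ``repressor_mask`` hold one bit per incoming
    activation / repression edge, in canonical (edge input) order.  Under
    ``one_site`` semantics at most one bit is set across both masks.
    """

    gene: str
    activator_mask: tuple[int, ...]
    repressor_mask: tuple[int, ...]
    semantics: Semantics = "per_site"

    def __post_init__(self) -> None:
        if self.semantics == "one_site":
            if sum(self.activator_mask) + sum(self.repressor_mask) > 1:
                raise ValueError(
                    "one_site semantics admits at most one bound regulator"
                )

    @property
    def n_bound(self) -> int:
        return sum(self.activator_mask) + sum(self.repressor_mask)

    @property
    def has_activator(self) -> bool:
        return any(self.activator_mask)

    @property
    def has_repressor(self) -> bool:
        return any(self.repressor_mask)

    def species_name(
        self, activators: Sequence[str] = (), repressors: Sequence[str] = ()
    ) -> str:
        """Deterministic species name for this state.

        per_site: ``<gene>_a<bits>_r<bits>`` (mask segments dropped when the
        gene has no sites of that kind); one_site: ``<gene>_free`` or
        ``<gene>_<regulator>``.
        """
        if self.semantics == "one_site":
            if self.n_bound == 0:
                return f"{self.gene}_free"
            for i, b in enumerate(self.activator_mask):
                if b:
                    return f"{self.gene}_{activators[i]}"
            for i, b in enumerate(self.repressor_mask):
                if b:
                    return f"{self.gene}_{repressors[i]}"
        parts = [self.gene]
        if self.activator_mask:
            parts.append("a" + "".join(str(b) for b in self.activator_mask))
        if self.repressor_mask:
            parts.append("r" + "".join(str(b) for b in self.repressor_mask))
        if len(parts) == 1:
            parts.append("gene")
        return "_".join(parts)


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with integer stoichiometries and a named rate.

    At most two reactant molecules in total (binary collisions): the
    mass-action flux is the rate constant times the product of reactant
    concentrations raised to their stoichiometries.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_name: str
    rate_value: float

    def __post_init__(self) -> None:
        if self.rate_value <= 0:
            raise ValueError(f"rate {self.rate_name} must be positive")
        if any(v < 0 for v in self.reactants.values()) or any(
            v < 0 for v in self.products.values()
        ):
            raise ValueError("stoichiometries must be non-negative")
        if sum(self.reactants.values()) > 2:
            raise ValueError(
                f"reaction {self.rate_name}: more than two reactant molecules "
                "(only binary collisions are modeled)"
            )

    def format(self) -> str:
        def side(stoich: Mapping[str, int]) -> str:
            if not stoich:
                return "0"
            return " + ".join(
                (f"{n} {s}" if n > 1 else s) for s, n in stoich.items()
            )

        return f"{side(self.reactants)} -{self.rate_name}-> {side(self.products)}"


@dataclass
class ReactionNetwork:
    """An ordered species list with mass-action reactions and parameters."""

    species: list[str]
    reactions: list[Reaction]
    parameters: dict[str, float]
    constant_species: set[str] = field(default_factory=set)
    initial_conditions: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        sset = set(self.species)
        if len(sset) != len(self.species):
            raise ValueError("duplicate species name")
        for r in self.reactions:
            for s in itertools.chain(r.reactants, r.products):
                if s not in sset:
                    raise ValueError(f"reaction {r.rate_name} references unknown species {s}")
        if len(self.parameters) != len(set(self.parameters)):
            raise ValueError("duplicate parameter name")

    def with_parameters(self, updates: Mapping[str, float]) -> "ReactionNetwork":
        """Copy of the network with some rate constants replaced."""
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(updates)
        reactions = [
            Reaction(r.reactants, r.products, r.rate_name, params[r.rate_name])
            for r in self.reactions
        ]
        return ReactionNetwork(
            list(self.species),
            reactions,
            params,
            set(self.constant_species),
            dict(self.initial_conditions),
        )

    def format(self) -> str:
        return "\n".join(r.format() for r in self.reactions) + "\n"


def enumerate_operon_states(
    gene: str,
    activators: Sequence[str],
    repressors: Sequence[str],
    semantics: Semantics = "per_site",
) -> list[OperonState]:
    """All operon occupancy states of a gene, in canonical order.

    per_site: the ``2**(a+r)`` masks in lexicographic order (activator bits
    vary slowest).  one_site: the free state, then one singly-bound state per
    regulator in activator-then-repressor input order.
    """
    a, r = len(activators), len(repressors)
    if semantics == "per_site":
        states = []
        for abits in itertools.product((0, 1), repeat=a):
            for rbits in itertools.product((0, 1), repeat=r):
                states.append(OperonState(gene, abits, rbits, "per_site"))
        return states
    if semantics == "one_site":
        states = [OperonState(gene, (0,) * a, (0,) * r, "one_site")]
        for i in range(a):
            mask = tuple(1 if j == i else 0 for j in range(a))
            states.append(OperonState(gene, mask, (0,) * r, "one_site"))
        for i in range(r):
            mask = tuple(1 if j == i else 0 for j in range(r))
            states.append(OperonState(gene, (0,) * a, mask, "one_site"))
        return states
    raise ValueError(f"unknown semantics {semantics!r}")


def _mask_tag(state: OperonState) -> str:
    parts = []
    if state.activator_mask:
        parts.append("a" + "".join(map(str, state.activator_mask)))
    if state.repressor_mask:
        parts.append("r" + "".join(map(str, state.repressor_mask)))
    return "".join(parts) or "basal"


def compile_reactions(
    graph: DoubleGraph,
    semantics: Semantics = "per_site",
    rate_defaults: Mapping[str, float] | None = None,
    rate_values: Mapping[str, float] | None = None,
) -> ReactionNetwork:
    """Compile a double graph into a mass-action :class:`ReactionNetwork`.

    For every gene the compiler emits, per binding site (per_site) or for
    the shared site (one_site), a reversible regulator binding/unbinding
    pair; a catalytic production reaction ``state -> state + protein`` for
    every state with at least one activator bound, with a state-specific
    rate; and a degradation reaction for every non-constant protein.  A gene
    with no activators at all produces at a basal rate from repressor-free
    states.  mRNA-annotated vertices are excluded from the kinetics and
    mRNA-sourced edges are treated as translation annotations, not
    reactions.

    Parameter naming is deterministic: ``kb_<gene>_<regulator>`` /
    ``ku_<gene>_<regulator>`` for binding and unbinding, ``kp_<gene>_<mask>``
    for production, ``kd_<protein>`` for degradation.

    ``rate_defaults`` overrides the per-class defaults (keys ``bind``,
    ``unbind``, ``production``, ``degradation``); ``rate_values`` overrides
    individual named parameters.
    """
    if semantics not in ("per_site", "one_site"):
        raise ValueError(f"unknown semantics {semantics!r}")
    defaults = dict(DEFAULT_RATES)
    if rate_defaults:
        unknown = set(rate_defaults) - set(defaults)
        if unknown:
            raise KeyError(f"unknown rate class(es): {sorted(unknown)}")
        defaults.update(rate_defaults)

    species: list[str] = []
    reactions: list[Reaction] = []
    parameters: dict[str, float] = {}
    constant: set[str] = set()
    initial: dict[str, float] = {}

    def add_species(name: str) -> None:
        if name not in species:
            species.append(name)

    def add_param(name: str, value: float) -> str:
        if rate_values and name in rate_values:
            value = rate_values[name]
        if name in parameters:
            raise ValueError(f"parameter name collision: {name}")
        parameters[name] = value
        return name

    dyn = graph.dynamic_vertices()

    def transcriptional_regulators(v: str) -> tuple[list[str], list[str]]:
        acts, reps = regulators_of(graph, v)
        not_mrna = lambda s: not graph.annotation(s).is_mrna
        return [s for s in acts if not_mrna(s)], [s for s in reps if not_mrna(s)]

    genes = [v for v in dyn if graph.is_gene(v)]

    # proteins and constant inputs first appear as plain species
    for v in dyn:
        add_species(v)
        if graph.annotation(v).constant_input:
            constant.add(v)
        ic = graph.annotation(v).initial_concentration
        if ic is not None:
            initial[v] = ic

    for gene in genes:
        activators, repressors = transcriptional_regulators(gene)
        states = enumerate_operon_states(gene, activators, repressors, semantics)
        names = {s: s.species_name(activators, repressors) for s in states}
        for s in states:
            add_species(names[s])

        regs = [(reg, "a", i) for i, reg in enumerate(activators)] + [
            (reg, "r", i) for i, reg in enumerate(repressors)
        ]
        if semantics == "per_site":
            for reg, kind, i in regs:
                kb = add_param(f"kb_{gene}_{reg}", defaults["bind"])
                ku = add_param(f"ku_{gene}_{reg}", defaults["unbind"])
                for s in states:
                    mask = s.activator_mask if kind == "a" else s.repressor_mask
                    if mask[i]:
                        continue
                    bound = _flip(s, kind, i)
                    reactions.append(
                        Reaction({reg: 1, names[s]: 1}, {names[bound]: 1}, kb,
                                 parameters[kb])
                    )
                    reactions.append(
                        Reaction({names[bound]: 1}, {reg: 1, names[s]: 1}, ku,
                                 parameters[ku])
                    )
        else:  # one_site: regulators compete for the shared site
            free = states[0]
            for s in states[1:]:
                reg = names[s].removeprefix(f"{gene}_")
                kb = add_param(f"kb_{gene}_{reg}", defaults["bind"])
                ku = add_param(f"ku_{gene}_{reg}", defaults["unbind"])
                reactions.append(
                    Reaction({reg: 1, names[free]: 1}, {names[s]: 1}, kb,
                             parameters[kb])
                )
                reactions.append(
                    Reaction({names[s]: 1}, {reg: 1, names[free]: 1}, ku,
                             parameters[ku])
                )

        # transcription+translation, lumped: catalytic production of protein
        if activators:
            producing = [s for s in states if s.has_activator]
        else:
            # unregulated or repressor-only gene: basal production from
            # repressor-free states
            producing = [s for s in states if not s.has_repressor]
        for s in producing:
            if semantics == "one_site":
                tag = names[s].removeprefix(f"{gene}_") if s.n_bound else "basal"
            else:
                tag = _mask_tag(s)
            kp = add_param(f"kp_{gene}_{tag}", defaults["production"])
            reactions.append(
                Reaction({names[s]: 1}, {names[s]: 1, gene: 1}, kp, parameters[kp])
            )

    # proteins always degrade; operon states never do
    for v in dyn:
        if v in constant:
            continue
        kd = add_param(f"kd_{v}", defaults["degradation"])
        reactions.append(Reaction({v: 1}, {}, kd, parameters[kd]))

    net = ReactionNetwork(species, reactions, parameters, constant, initial)
    net.validate()
    return net


def _flip(state: OperonState, kind: str, i: int) -> OperonState:
    if kind == "a":
        mask = list(state.activator_mask)
        mask[i] = 1
        return OperonState(state.gene, tuple(mask), state.repressor_mask,
                           state.semantics)
    mask = list(state.repressor_mask)
    mask[i] = 1
    return OperonState(state.gene, state.activator_mask, tuple(mask),
                       state.semantics)


def operon_species_of(
    network: ReactionNetwork, graph: DoubleGraph, gene: str,
    semantics: Semantics = "per_site",
) -> list[str]:
    """Names of the operon-state species belonging to one gene."""
    acts, reps = regulators_of(graph, gene)
    not_mrna = lambda s: not graph.annotation(s).is_mrna
    acts = [s for s in acts if not_mrna(s)]
    reps = [s for s in reps if not_mrna(s)]
    states = enumerate_operon_states(gene, acts, reps, semantics)
    return [s.species_name(acts, reps) for s in states]


def expected_reaction_count(
    n_activators: int, n_repressors: int, semantics: Semantics
) -> int:
    """Closed-form reaction count for a single regulated gene (excl. the
    protein degradation shared with the backbone)."""
    a, r = n_activators, n_repressors
    n = a + r
    if semantics == "per_site":
        binding = 2 * n * 2 ** (n - 1) if n else 0
        if a:
            producing = (2**a - 1) * 2**r
        else:
            producing = 1  # basal from the repressor-free state
        return binding + producing
    binding = 2 * n
    producing = a if a else 1
    return binding + producing
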