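"""Mass-action ODE systems, stoichiometric matrices and conservation laws.

Given a reaction network, the mass action law yields the polynomial system

    dX/dt = Gamma . v(X),   v_j(X) = k_j * prod_i X_i^{alpha_ij},

where ``alpha``/``beta`` are reactant/product stoichiometries and
``Gamma = beta - alpha`` is the stoichiometric matrix over the *state*
species (constant inputs appear inside fluxes as fixed numbers and get no
row).  Every vector ``c`` in the left null space of Gamma gives a linear
conservation law ``c . X = const`` fixed by the initial condition; for
compiled regulatory networks these are precisely the gene totals, because
operon states are perfect catalysts.

The null space is computed in exact rational arithmetic so conservation
laws are bit-stable across runs; vectors are scaled to coprime integers
with a positive leading entry and ordered by pivot column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .regulation_compiler import Reaction, ReactionNetwork

__all__ = [
    "Flux",
    "ODESystem",
    "ConservationLaw",
    "build_odes",
    "conservation_laws",
    "reduce_by_conservation",
    "ReducedODESystem",
]


@dataclass(frozen=True)
class Flux:
    """One mass-action flux monomial: ``rate * prod(conc ** power)``."""

    rate_name: str
    rate_value: float
    state_powers: tuple[tuple[int, int], ...]   # (state index, power)
    constant_factor: float                      # product of constant-species terms

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [self.rate_name]
        for i, p in self.state_powers:
            parts.append(f"x{i}" + (f"^{p}" if p > 1 else ""))
        return "*".join(parts)


class ConfigurationError(ValueError):
    """A constant species lacks a concentration value."""


@dataclass
class ODESystem:
    """Polynomial mass-action vector field in matrix form.

    ``rhs(x)`` evaluates ``Gamma @ v(x)``; constant species are parameters,
    not state, and can be overridden per evaluation (used for spatial
    profiles of fixed regulators).
    """

    state_species: list[str]
    constant_species: list[str]
    constant_values: dict[str, float]
    fluxes: list[Flux]
    stoich_matrix: np.ndarray           # int matrix, species x reactions
    initial_conditions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.state_species)}
        ns, nr = self.stoich_matrix.shape
        assert ns == len(self.state_species) and nr == len(self.fluxes)

    @property
    def n_state(self) -> int:
        return len(self.state_species)

    def species_index(self, name: str) -> int:
        return self._index[name]

    def _flux_constants(
        self, constants: Mapping[str, float] | None
    ) -> np.ndarray:
        if constants is None:
            return np.array([f.constant_factor for f in self.fluxes])
        out = np.empty(len(self.fluxes))
        for j, f in enumerate(self.fluxes):
            c = 1.0
            for name, power in getattr(f, "_constant_powers", ()):
                c *= constants.get(name, self.constant_values[name]) ** power
            out[j] = c
        return out

    def flux_values(
        self, x: np.ndarray, constants: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Vector of flux monomial values at state ``x``.

        ``x`` may be shape ``(n_state,)`` or ``(n_state, m)`` for ``m``
        simultaneous (e.g. spatial) copies of the system.
        """
        x = np.asarray(x, dtype=float)
        batch = x.ndim == 2
        m = x.shape[1] if batch else 1
        v = np.empty((len(self.fluxes), m) if batch else len(self.fluxes))
        cf = self._flux_constants(constants)
        for j, f in enumerate(self.fluxes):
            val = f.rate_value * cf[j]
            term = val if not batch else np.full(m, val)
            for i, p in f.state_powers:
                term = term * (x[i] ** p)
            v[j] = term
        return v

    def rhs(
        self, x: np.ndarray, constants: Mapping[str, float] | None = None
    ) -> np.ndarray:
        return self.stoich_matrix @ self.flux_values(x, constants)

    def jacobian(
        self, x: np.ndarray, constants: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Analytic Jacobian of the polynomial rhs at ``x`` (1-D state only)."""
        x = np.asarray(x, dtype=float)
        n = self.n_state
        dv = np.zeros((len(self.fluxes), n))
        cf = self._flux_constants(constants)
        for j, f in enumerate(self.fluxes):
            for i, p in f.state_powers:
                term = f.rate_value * cf[j] * p * x[i] ** (p - 1)
                for i2, p2 in f.state_powers:
                    if i2 != i:
                        term = term * x[i2] ** p2
                dv[j, i] += term
        return self.stoich_matrix @ dv

    # -- symbolic view ---------------------------------------------------

    def to_sympy(self, numeric_rates: bool = False):
        """Symbolic (state symbols, rhs expressions) pair."""
        syms = [sp.Symbol(_safe(s)) for s in self.state_species]
        exprs = []
        for i in range(self.n_state):
            e = sp.Integer(0)
            for j, f in enumerate(self.fluxes):
                g = int(self.stoich_matrix[i, j])
                if g == 0:
                    continue
                if numeric_rates:
                    mono = sp.Float(f.rate_value) * sp.Float(f.constant_factor)
                else:
                    mono = sp.Symbol(f.rate_name, positive=True) * sp.Float(
                        f.constant_factor
                    ) if f.constant_factor != 1.0 else sp.Symbol(
                        f.rate_name, positive=True
                    )
                for k, p in f.state_powers:
                    mono *= syms[k] ** p
                e += g * mono
            exprs.append(sp.expand(e))
        return syms, exprs

    def format(self) -> str:
        syms, exprs = self.to_sympy()
        return "\n".join(
            f"d{self.state_species[i]}/dt = {sp.sstr(exprs[i])}"
            for i in range(self.n_state)
        ) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_species": self.state_species,
                "constant_species": self.constant_species,
                "stoich_matrix": self.stoich_matrix.tolist(),
                "fluxes": [
                    {
                        "rate_name": f.rate_name,
                        "rate_value": f.rate_value,
                        "state_powers": [list(t) for t in f.state_powers],
                        "constant_factor": f.constant_factor,
                    }
                    for f in self.fluxes
                ],
            },
            indent=2,
        )

    def initial_state(
        self, overrides: Mapping[str, float] | None = None
    ) -> np.ndarray:
        x0 = np.zeros(self.n_state)
        for name, v in self.initial_conditions.items():
            if name in self._index:
                x0[self._index[name]] = v
        if overrides:
            for name, v in overrides.items():
                x0[self._index[name]] = v
        return x0


def _safe(name: str) -> str:
    return name.replace("-", "_")


def build_odes(network: ReactionNetwork) -> ODESystem:
    """Derive the polynomial ODE system for a reaction network.

    Constant species must carry a value (from initial conditions or a
    default of 1.0 is *not* assumed — missing values raise
    :class:`ConfigurationError`); they are folded into the flux constants
    and excluded from the stoichiometric matrix, where they would otherwise
    generate spurious conservation laws.
    """
    network.validate()
    constant = sorted(network.constant_species)
    state = [s for s in network.species if s not in network.constant_species]
    index = {s: i for i, s in enumerate(state)}

    const_values: dict[str, float] = {}
    for s in constant:
        if s in network.initial_conditions:
            const_values[s] = network.initial_conditions[s]
        else:
            raise ConfigurationError(
                f"constant species {s!r} has no concentration value; set an "
                "initial condition for it"
            )

    fluxes: list[Flux] = []
    gamma = np.zeros((len(state), len(network.reactions)), dtype=int)
    for j, r in enumerate(network.reactions):
        powers: list[tuple[int, int]] = []
        cpowers: list[tuple[str, int]] = []
        cfactor = 1.0
        for s, a in r.reactants.items():
            if a == 0:
                continue
            if s in network.constant_species:
                cpowers.append((s, a))
                cfactor *= const_values[s] ** a
            else:
                powers.append((index[s], a))
        f = Flux(r.rate_name, r.rate_value, tuple(sorted(powers)), cfactor)
        object.__setattr__(f, "_constant_powers", tuple(cpowers))
        fluxes.append(f)
        for s, a in r.reactants.items():
            if s in index:
                gamma[index[s], j] -= a
        for s, b in r.products.items():
            if s in index:
                gamma[index[s], j] += b

    return ODESystem(
        state_species=state,
        constant_species=constant,
        constant_values=const_values,
        fluxes=fluxes,
        stoich_matrix=gamma,
        initial_conditions={
            k: v for k, v in network.initial_conditions.items() if k in index
        },
    )


@dataclass(frozen=True)
class ConservationLaw:
    """An integer left-null vector of Gamma with its trajectory constant."""

    coefficients: tuple[int, ...]
    constant: float | None = None
    species: tuple[str, ...] = ()

    def value(self, x: Sequence[float]) -> float:
        return float(np.dot(self.coefficients, x))

    def format(self) -> str:
        terms = []
        for c, s in zip(self.coefficients, self.species):
            if c == 0:
                continue
            if c == 1:
                terms.append(s)
            elif c == -1:
                terms.append(f"-{s}")
            else:
                terms.append(f"{c}*{s}")
        lhs = " + ".join(terms).replace("+ -", "- ")
        rhs = "const" if self.constant is None else f"{self.constant:g}"
        return f"{lhs} = {rhs}"


def conservation_laws(
    odesys: ODESystem, initial: Mapping[str, float] | None = None
) -> list[ConservationLaw]:
    """Canonical basis of linear conservation laws of the system.

    Computed as the null space of ``Gamma.T`` over the rationals (reduced
    row echelon form), then scaled to coprime integers with positive leading
    coefficient.  Constants are evaluated from ``initial`` (falling back to
    the system's stored initial conditions); they are ``None`` when no
    initial state is known.
    """
    gamma = sp.Matrix(odesys.stoich_matrix.tolist())
    basis = gamma.T.nullspace()
    laws = []
    for vec in basis:
        fracs = [Fraction(sp.Rational(v).p, sp.Rational(v).q) for v in vec]
        den = 1
        for f in fracs:
            den = den * f.denominator // gcd(den, f.denominator)
        ints = [int(f * den) for f in fracs]
        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        lead = next((v for v in ints if v != 0), 1)
        if lead < 0:
            ints = [-v for v in ints]
        laws.append(ints)
    # deterministic order: by pivot (first nonzero) column
    laws.sort(key=lambda v: next(i for i, c in enumerate(v) if c != 0))

    ics = dict(odesys.initial_conditions)
    if initial:
        ics.update(initial)
    out = []
    for ints in laws:
        const = None
        if ics:
            x0 = np.array([ics.get(s, 0.0) for s in odesys.state_species])
            const = float(np.dot(ints, x0))
        out.append(
            ConservationLaw(tuple(ints), const, tuple(odesys.state_species))
        )
    return out


class EliminationError(ValueError):
    pass


class ReducedODESystem:
    """An ODE system with conservation laws substituted in.

    Each chosen species is replaced throughout the remaining equations by
    ``(constant - sum(other terms)) / coefficient``; the reduced state is
    the complement of the eliminated set.  The vector field and Jacobian are
    exact (chain rule through the affine reconstruction), and eliminated
    coordinates can be reconstructed from any reduced state.
    """

    def __init__(
        self,
        parent: ODESystem,
        laws: Sequence[ConservationLaw],
        eliminate: Sequence[str],
        constants: Sequence[float] | None = None,
    ) -> None:
        if len(laws) != len(eliminate):
            raise EliminationError("one species must be chosen per law")
        self.parent = parent
        self.laws = list(laws)
        self.eliminated = list(eliminate)
        consts = []
        for law, sp_name in zip(laws, eliminate):
            c = law.constant
            if constants is not None:
                c = constants[len(consts)]
            if c is None:
                raise EliminationError(
                    f"law for {sp_name} has no constant; supply one"
                )
            i = parent.species_index(sp_name)
            if law.coefficients[i] == 0:
                raise EliminationError(
                    f"species {sp_name!r} has zero coefficient in its law"
                )
            consts.append(float(c))
        self.constants = consts
        self.state_species = [
            s for s in parent.state_species if s not in set(eliminate)
        ]
        self._keep_idx = np.array(
            [parent.species_index(s) for s in self.state_species], dtype=int
        )
        self._elim_idx = np.array(
            [parent.species_index(s) for s in eliminate], dtype=int
        )
        # solve the affine system  L_e x_e = c - L_k x_k  for the eliminated
        # coordinates as a function of the kept ones
        L = np.array([law.coefficients for law in laws], dtype=float)
        Le = L[:, self._elim_idx]
        Lk = L[:, self._keep_idx]
        if abs(np.linalg.det(Le)) < 1e-12:
            raise EliminationError(
                "chosen species are not independently eliminable"
            )
        Le_inv = np.linalg.inv(Le)
        self._recon_A = -Le_inv @ Lk          # x_e = A x_k + b
        self._recon_b = Le_inv @ np.array(consts)

    @property
    def n_state(self) -> int:
        return len(self.state_species)

    def species_index(self, name: str) -> int:
        return self.state_species.index(name)

    def full_state(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        x = np.zeros(self.parent.n_state)
        x[self._keep_idx] = y
        x[self._elim_idx] = self._recon_A @ y + self._recon_b
        return x

    def rhs(self, y: np.ndarray, constants=None) -> np.ndarray:
        return self.parent.rhs(self.full_state(y), constants)[self._keep_idx]

    def jacobian(self, y: np.ndarray, constants=None) -> np.ndarray:
        Jfull = self.parent.jacobian(self.full_state(y), constants)
        Jk = Jfull[np.ix_(self._keep_idx, self._keep_idx)]
        Je = Jfull[np.ix_(self._keep_idx, self._elim_idx)]
        return Jk + Je @ self._recon_A

    def to_sympy(self):
        syms_full, exprs_full = self.parent.to_sympy()
        keep_syms = [syms_full[i] for i in self._keep_idx]
        subs = {}
        for row, i in enumerate(self._elim_idx):
            expr = sp.nsimplify(self._recon_b[row], rational=True)
            for col, k in enumerate(self._keep_idx):
                a = sp.nsimplify(self._recon_A[row, col], rational=True)
                expr += a * syms_full[k]
            subs[syms_full[i]] = expr
        exprs = [sp.expand(exprs_full[i].subs(subs)) for i in self._keep_idx]
        return keep_syms, exprs


def reduce_by_conservation(
    odesys: ODESystem,
    laws: Sequence[ConservationLaw],
    eliminate: Sequence[str],
    constants: Sequence[float] | None = None,
) -> ReducedODESystem:
    """Eliminate one species per conservation law from the system."""
    return ReducedODESystem(odesys, laws, eliminate, constants)
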