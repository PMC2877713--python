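"""Spatial patterning from non-homogeneous regulator profiles.

Position enters the model only through initial/constant concentrations:
regulator profiles vary along a scaled 1-D axis x in [0, 1], every position
integrates the same ODE system independently, and there is no diffusion,
advection or any other coupling between positions.  Localized expression
domains then arise purely from the concentration-dependent thresholds of
the regulatory kinetics.

For networks whose regulators are all held constant the kinetics are
affine-linear in the state, and the per-position steady state is obtained
in closed form by solving the conservation-reduced linear system.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dynamics import integrate, integrate_fixed_grid
from .mass_action import (
    ODESystem,
    build_odes,
    conservation_laws,
)
from .regulation_compiler import ReactionNetwork

__all__ = [
    "SpatialProfile",
    "SpatialField",
    "simulate_field",
    "linear_steady_state",
    "NonlinearSystemError",
]


class NonlinearSystemError(ValueError):
    """The closed-form linear solver was applied to a nonlinear system."""


@dataclass(frozen=True)
class SpatialProfile:
    """A sampled concentration profile over scaled embryo position.

    Positions are strictly increasing in [0, 1]; values are non-negative
    concentrations in arbitrary units; ``sd`` optionally holds per-point
    measurement standard deviations.
    """

    positions: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if p.shape != v.shape:
            raise ValueError("positions and values must have the same length")
        if self.sd is not None and self.sd.shape != p.shape:
            raise ValueError("sd must match positions in length")
        if len(p) and (np.any(np.diff(p) <= 0)):
            raise ValueError("positions must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        header = ["position", "value"] + (["sd"] if self.sd is not None else [])
        w.writerow(header)
        for i in range(len(self)):
            row = [f"{self.positions[i]:.10g}", f"{self.values[i]:.10g}"]
            if self.sd is not None:
                row.append(f"{self.sd[i]:.10g}")
            w.writerow(row)
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "SpatialProfile":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
        rows = list(csv.reader(lines))
        if rows and not _is_number(rows[0][0]):
            rows = rows[1:]
        rows = [r for r in rows if r]
        pos = np.array([float(r[0]) for r in rows])
        val = np.array([float(r[1]) for r in rows])
        sd = None
        if rows and len(rows[0]) > 2:
            sd = np.array([float(r[2]) for r in rows])
        return cls(pos, val, sd)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


class SpatialField(dict):
    """Mapping species -> :class:`SpatialProfile` on a shared position grid."""

    def __init__(self, profiles: Mapping[str, SpatialProfile]):
        super().__init__(profiles)
        grids = [p.positions for p in self.values()]
        for g in grids[1:]:
            if not np.array_equal(g, grids[0]):
                raise ValueError("all profiles must share one position grid")

    @property
    def positions(self) -> np.ndarray:
        return next(iter(self.values())).positions

    def values_matrix(self, species: Sequence[str]) -> np.ndarray:
        """(len(species), n_positions) array of profile values."""
        return np.stack([self[s].values for s in species])

    def to_wide_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        names = list(self.keys())
        w.writerow(["position"] + names)
        pos = self.positions
        for i in range(len(pos)):
            w.writerow([f"{pos[i]:.10g}"] + [f"{self[n].values[i]:.10g}" for n in names])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_wide_csv(cls, source: str | Path) -> "SpatialField":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
        rows = list(csv.reader(lines))
        names = rows[0][1:]
        data = np.array([[float(v) for v in r] for r in rows[1:]])
        pos = data[:, 0]
        return cls({
            n: SpatialProfile(pos, data[:, i + 1]) for i, n in enumerate(names)
        })


DEFAULT_GRID = np.linspace(0.0, 1.0, 100)


def _prepare(network: ReactionNetwork) -> ODESystem:
    net = network
    missing = [
        s for s in net.constant_species if s not in net.initial_conditions
    ]
    if missing:
        # spatial inputs supply the values; placeholder keeps build_odes happy
        net = ReactionNetwork(
            list(net.species), list(net.reactions), dict(net.parameters),
            set(net.constant_species),
            {**{m: 0.0 for m in missing}, **net.initial_conditions},
        )
    return build_odes(net)


def simulate_field(
    network: ReactionNetwork,
    inputs: SpatialField,
    gene_totals: Mapping[str, Mapping[str, float] | float],
    t_final: float,
    initial_proteins: SpatialField | None = None,
    method: str = "batch_rk4",
    n_steps: int = 600,
) -> SpatialField:
    """Integrate the network independently at every spatial position.

    ``inputs`` must provide a profile for every constant species.
    ``gene_totals`` maps each gene's *free* operon-state species name to its
    total concentration (scalar, uniform in space); all gene copies start in
    the free state.  ``initial_proteins`` optionally sets position-dependent
    initial protein concentrations (e.g. maternal gradients).

    ``method='batch_rk4'`` advances all positions in lockstep with a
    vectorized fixed-step integrator; ``method='lsoda'`` loops positions
    through the adaptive stiff solver (slower, used as accuracy reference).
    """
    odesys = _prepare(network)
    missing = [s for s in odesys.constant_species if s not in inputs]
    if missing:
        raise KeyError(f"missing input profile(s) for constant species {missing}")
    pos = inputs.positions
    m = len(pos)

    x0 = np.zeros((odesys.n_state, m))
    for name, value in gene_totals.items():
        x0[odesys.species_index(name)] = value
    if initial_proteins:
        for name, prof in initial_proteins.items():
            if not np.array_equal(prof.positions, pos):
                raise ValueError("initial protein grid differs from input grid")
            x0[odesys.species_index(name)] = prof.values

    const_mat = inputs.values_matrix(odesys.constant_species)

    if method == "batch_rk4":
        xf = _integrate_batch(odesys, x0, const_mat, t_final, n_steps)
    elif method == "lsoda":
        xf = np.empty_like(x0)
        for k in range(m):
            consts = {
                s: const_mat[i, k] for i, s in enumerate(odesys.constant_species)
            }
            traj = integrate(odesys, x0[:, k], t_final, constants=consts)
            xf[:, k] = traj.final
    else:
        raise ValueError(f"unknown method {method!r}")

    return SpatialField({
        s: SpatialProfile(pos, np.clip(xf[odesys.species_index(s)], 0, None))
        for s in odesys.state_species
    })


def _integrate_batch(
    odesys: ODESystem,
    x0: np.ndarray,
    const_mat: np.ndarray,
    t_final: float,
    n_steps: int,
) -> np.ndarray:
    """Vectorized RK4 over all positions at once.

    Constant-species profiles are baked into per-position flux prefactors,
    so one rhs evaluation covers every position.
    """
    n_flux = len(odesys.fluxes)
    m = x0.shape[1]
    pref = np.empty((n_flux, m))
    cindex = {s: i for i, s in enumerate(odesys.constant_species)}
    for j, f in enumerate(odesys.fluxes):
        c = np.full(m, f.rate_value)
        for name, power in getattr(f, "_constant_powers", ()):
            c = c * const_mat[cindex[name]] ** power
        pref[j] = c
    gamma = odesys.stoich_matrix.astype(float)

    def rhs(x: np.ndarray) -> np.ndarray:
        v = pref.copy()
        for j, f in enumerate(odesys.fluxes):
            for i, p in f.state_powers:
                v[j] *= x[i] ** p
        return gamma @ v

    x = x0.copy()
    h = float(t_final) / n_steps
    for _ in range(n_steps):
        k1 = rhs(x)
        k2 = rhs(np.clip(x + 0.5 * h * k1, 0.0, None))
        k3 = rhs(np.clip(x + 0.5 * h * k2, 0.0, None))
        k4 = rhs(np.clip(x + h * k3, 0.0, None))
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(x, 0.0, None, out=x)
    return x


def linear_steady_state(
    network: ReactionNetwork,
    inputs: SpatialField,
    gene_totals: Mapping[str, float],
) -> SpatialField:
    """Closed-form per-position steady state of an affine-linear network.

    Applicable when every regulator is a constant-input species, so each
    flux is at most first order in the state.  The conservation laws (gene
    totals) are substituted first; the resulting reduced linear system
    ``A y + b = 0`` is solved exactly at each position and the eliminated
    operon coordinates are reconstructed.

    Raises :class:`NonlinearSystemError` when any flux is of second order
    in the state variables.
    """
    odesys = _prepare(network)
    for f in odesys.fluxes:
        if sum(p for _, p in f.state_powers) > 1:
            raise NonlinearSystemError(
                f"flux {f.rate_name} is nonlinear in the state; "
                "linear_steady_state requires all regulators constant"
            )
    pos = inputs.positions
    m = len(pos)
    const_mat = inputs.values_matrix(odesys.constant_species)
    cindex = {s: i for i, s in enumerate(odesys.constant_species)}

    laws = conservation_laws(odesys)
    x0 = np.zeros(odesys.n_state)
    for name, value in gene_totals.items():
        x0[odesys.species_index(name)] = value
    law_consts = [float(np.dot(l.coefficients, x0)) for l in laws]
    elim = [_pick_eliminable(l, odesys) for l in laws]

    n = odesys.n_state
    out = np.empty((n, m))
    for k in range(m):
        consts = {s: const_mat[cindex[s], k] for s in odesys.constant_species}
        # affine rhs: f(x) = A x + b
        b = odesys.rhs(np.zeros(n), consts)
        A = odesys.jacobian(np.zeros(n), consts)
        if laws:
            keep = [i for i in range(n) if i not in [odesys.species_index(e) for e in elim]]
            eidx = [odesys.species_index(e) for e in elim]
            L = np.array([l.coefficients for l in laws], dtype=float)
            Le, Lk = L[:, eidx], L[:, keep]
            Le_inv = np.linalg.inv(Le)
            R_A = -Le_inv @ Lk
            R_b = Le_inv @ np.array(law_consts)
            Ar = A[np.ix_(keep, keep)] + A[np.ix_(keep, eidx)] @ R_A
            br = b[keep] + A[np.ix_(keep, eidx)] @ R_b
            y = np.linalg.solve(Ar, -br)
            x = np.zeros(n)
            x[keep] = y
            x[eidx] = R_A @ y + R_b
        else:
            x = np.linalg.solve(A, -b)
        out[:, k] = x

    return SpatialField({
        s: SpatialProfile(pos, np.clip(out[odesys.species_index(s)], 0, None))
        for s in odesys.state_species
    })


def _pick_eliminable(law, odesys) -> str:
    for i, c in enumerate(law.coefficients):
        if c != 0:
            return odesys.state_species[i]
    raise ValueError("zero conservation vector")
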