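"""Numerical dynamics: integration, steady states, threshold bifurcation.

The central phenomenon this module exposes is the emergent concentration
threshold of self-activating genes: because operon states are catalysts,
every gene contributes a conservation law (total gene concentration C), and
C acts as a bifurcation parameter.  Below a critical total C* the only
stable steady state has zero protein; above it the zero branch loses
stability to a positive branch in a transcritical bifurcation — a threshold
that emerges from mass-action kinetics instead of being imposed through an
ad-hoc response function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .mass_action import ODESystem, ReducedODESystem

__all__ = [
    "Trajectory",
    "SteadyState",
    "BifurcationScan",
    "integrate",
    "integrate_fixed_grid",
    "find_steady_states",
    "threshold_scan",
]

AnySystem = ODESystem | ReducedODESystem

#: stability margin: eigenvalues within this of the imaginary axis are
#: classified as marginal rather than stable/unstable
STABILITY_MARGIN = 1e-9


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray          # (n_times, n_state)
    species: list[str]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class SteadyState:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stability: Literal["stable", "unstable", "marginal"]

    @property
    def leading_real(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass
class BifurcationScan:
    parameter: str
    grid: np.ndarray
    states: list[list[SteadyState]]
    critical_value: float | None

    def stable_branch(self, coord: int) -> np.ndarray:
        """Coordinate ``coord`` of the stable steady state at each grid
        value (NaN where no stable state was found)."""
        out = np.full(len(self.grid), np.nan)
        for i, sts in enumerate(self.states):
            stable = [s for s in sts if s.stability == "stable"]
            if stable:
                out[i] = max(s.coordinates[coord] for s in stable)
        return out


def integrate(
    odesys: AnySystem,
    initial_conditions: Sequence[float] | Mapping[str, float],
    t_final: float,
    t_eval: Sequence[float] | None = None,
    constants: Mapping[str, float] | None = None,
    method: str = "LSODA",
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the system with a stiff-capable adaptive solver.

    ``initial_conditions`` is either a full state vector or a mapping from
    species name to value (unnamed species start at 0).  Concentrations are
    kept effectively non-negative by tight tolerances; tiny negative
    excursions are clipped to 0 in the returned trajectory.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    if isinstance(initial_conditions, Mapping):
        x0 = np.zeros(odesys.n_state)
        for name, v in initial_conditions.items():
            x0[odesys.species_index(name)] = v
    else:
        x0 = np.asarray(initial_conditions, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial conditions must be non-negative")

    sol = solve_ivp(
        lambda t, y: odesys.rhs(y, constants),
        (0.0, float(t_final)),
        x0,
        method=method,
        jac=lambda t, y: odesys.jacobian(y, constants),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        dense_output=t_eval is None,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0}: "
            f"{sol.message}"
        )
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(sol.t, states, list(odesys.state_species))


def integrate_fixed_grid(
    odesys: AnySystem,
    x0: np.ndarray,
    t_final: float,
    n_steps: int = 400,
    constants: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Fast fixed-step RK4 endpoint integration.

    Supports batched states of shape ``(n_state, m)`` — m independent
    copies of the system (e.g. spatial positions) advanced in lockstep
    with vectorized flux evaluation.  Intended for the smooth, non-stiff
    parameter regimes of the calibration loop; accuracy against the
    adaptive solver is checked in the test suite.
    """
    x = np.asarray(x0, dtype=float).copy()
    h = float(t_final) / n_steps
    f = lambda y: odesys.rhs(y, constants)
    for _ in range(n_steps):
        k1 = f(x)
        k2 = f(np.clip(x + 0.5 * h * k1, 0.0, None))
        k3 = f(np.clip(x + 0.5 * h * k2, 0.0, None))
        k4 = f(np.clip(x + h * k3, 0.0, None))
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(x, 0.0, None, out=x)
    return x


def _classify(eigs: np.ndarray) -> str:
    m = float(np.max(eigs.real)) if len(eigs) else 0.0
    if m < -STABILITY_MARGIN:
        return "stable"
    if m > STABILITY_MARGIN:
        return "unstable"
    return "marginal"


def find_steady_states(
    odesys: AnySystem,
    n_starts: int = 50,
    bounds: tuple[float, float] = (1e-4, 1e2),
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
    constants: Mapping[str, float] | None = None,
    tol: float = 1e-11,
    dedup_tol: float = 1e-8,
) -> list[SteadyState]:
    """Locate non-negative steady states by multistart root-finding.

    Starts are log-uniform in ``bounds`` plus the origin and any
    ``extra_starts``; roots are polished with a damped Newton (hybr),
    deduplicated at ``dedup_tol`` and classified from the analytic Jacobian
    spectrum.  Works on full or conservation-reduced systems; for a reduced
    system the roots are steady states of the constrained dynamics.
    """
    rng = np.random.default_rng(seed)
    n = odesys.n_state
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    starts = [np.zeros(n)]
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    for _ in range(n_starts):
        starts.append(10.0 ** rng.uniform(lo, hi, size=n))

    found: list[np.ndarray] = []
    for s in starts:
        res = root(
            lambda y: odesys.rhs(y, constants),
            s,
            jac=lambda y: odesys.jacobian(y, constants),
            method="hybr",
            tol=tol,
        )
        if not res.success:
            continue
        y = res.x
        if np.any(y < -1e-9):
            continue
        y = np.clip(y, 0.0, None)
        if np.linalg.norm(odesys.rhs(y, constants)) > 1e-8:
            continue
        scale = 1.0 + np.linalg.norm(y)
        if any(np.linalg.norm(y - z) <= dedup_tol * scale for z in found):
            continue
        found.append(y)

    if not found:
        warnings.warn("no steady state found from any start")
    out = []
    for y in found:
        eigs = np.linalg.eigvals(odesys.jacobian(y, constants))
        out.append(SteadyState(y, eigs, _classify(eigs)))
    out.sort(key=lambda s: tuple(np.round(s.coordinates, 10)))
    return out


def threshold_scan(
    odesys_builder: Callable[[float], AnySystem],
    c_range: tuple[float, float],
    n_grid: int = 25,
    protein_index: int | None = None,
    trivial_guess: np.ndarray | None = None,
    seed: int = 0,
    rel_tol: float = 1e-6,
) -> BifurcationScan:
    """Scan a conservation constant C and locate the transcritical point.

    ``odesys_builder(C)`` must return the conservation-reduced system at
    gene total C.  The trivial (zero-protein) branch is tracked by
    root-finding from the origin; C* is found by bisection on the sign of
    the leading Jacobian eigenvalue along that branch, to relative
    tolerance ``rel_tol``.  If the leading eigenvalue has the same sign
    across the whole range, no threshold is reported.
    """
    lo, hi = c_range
    if not (0 < lo < hi):
        raise ValueError("c_range must be positive and increasing")
    if n_grid < 3:
        raise ValueError("n_grid must be at least 3")
    grid = np.linspace(lo, hi, n_grid)

    def trivial_state(C: float) -> tuple[np.ndarray, float]:
        sys_c = odesys_builder(C)
        guess = (
            np.zeros(sys_c.n_state) if trivial_guess is None
            else np.asarray(trivial_guess, dtype=float)
        )
        res = root(lambda y: sys_c.rhs(y), guess, jac=lambda y: sys_c.jacobian(y),
                   method="hybr", tol=1e-12)
        y = np.clip(res.x, 0.0, None)
        lead = float(np.max(np.linalg.eigvals(sys_c.jacobian(y)).real))
        return y, lead

    states = [
        find_steady_states(odesys_builder(C), seed=seed) for C in grid
    ]

    f = lambda C: trivial_state(C)[1]
    f_lo, f_hi = f(lo), f(hi)
    critical = None
    if f_lo * f_hi < 0:
        critical = float(
            brentq(f, lo, hi, rtol=rel_tol, xtol=rel_tol * lo)
        )
    return BifurcationScan("C", grid, states, critical)
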