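"""Synthetic anterior-posterior profiles emulating quantified embryo data.

Real gap-gene studies use databases of background-removed, registered
protein profiles along the scaled embryo axis (e.g. FlyEx).  This module
generates qualitatively matching synthetic stand-ins so the whole pipeline
— forward simulation, calibration, recovery tests — runs without any
download:

* BCD: anterior-high exponential gradient,
* maternal HB: anterior-high sigmoid,
* TLL: posterior Gaussian bump (optionally a small anterior one),

plus heteroscedastic Gaussian measurement noise, clipped at zero.  Shapes
and default parameters are fixture choices in arbitrary concentration
units; they reproduce the qualitative geometry of cycle 13/14 gradients,
not any particular embryo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .gapgene import GapGeneModel, build_gapgene_model, predict_profiles
from .spatial import SpatialField, SpatialProfile

__all__ = [
    "ProfileSpec",
    "NoiseSpec",
    "DEFAULT_INPUT_SPECS",
    "TRUTH_PARAMETERS",
    "TRUTH_GENE_TOTALS",
    "TRUTH_T",
    "generate_inputs",
    "generate_ground_truth",
    "default_grid",
    "FIT_BOUNDS",
    "gapgene_fit_problem",
    "truth_model",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise with sd = base + relative * value, clipped at 0."""

    base: float = 0.02
    relative: float = 0.05

    def sd(self, values: np.ndarray) -> np.ndarray:
        return self.base + self.relative * np.asarray(values)


@dataclass(frozen=True)
class ProfileSpec:
    """Parametric profile family on x in [0, 1].

    families: ``exponential`` A*exp(-x/w); ``sigmoid`` A/(1+exp((x-c)/w));
    ``gaussian_bump`` sum of A_i*exp(-(x-c_i)^2/(2 w_i^2)); ``flat`` A.
    """

    family: str
    amplitudes: tuple[float, ...] = (1.0,)
    centers: tuple[float, ...] = (0.5,)
    widths: tuple[float, ...] = (0.1,)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        A = self.amplitudes
        if self.family == "exponential":
            return A[0] * np.exp(-x / self.widths[0])
        if self.family == "sigmoid":
            return A[0] / (1.0 + np.exp((x - self.centers[0]) / self.widths[0]))
        if self.family == "gaussian_bump":
            out = np.zeros_like(x)
            for a, c, w in zip(A, self.centers, self.widths):
                out += a * np.exp(-((x - c) ** 2) / (2 * w**2))
            return out
        if self.family == "flat":
            return np.full_like(x, A[0])
        raise ValueError(f"unknown profile family {self.family!r}")


#: Default input gradients: anterior-high BCD with decay length 0.2,
#: maternal HB sigmoid stepping down near mid-embryo, TLL peaked in the
#: posterior with a small anterior shoulder.
DEFAULT_INPUT_SPECS: dict[str, ProfileSpec] = {
    "BCD": ProfileSpec("exponential", amplitudes=(4.0,), widths=(0.2,)),
    "HB_maternal": ProfileSpec(
        "sigmoid", amplitudes=(2.0,), centers=(0.45,), widths=(0.05,)
    ),
    "TLL": ProfileSpec(
        "gaussian_bump",
        amplitudes=(3.0, 0.6),
        centers=(0.88, 0.03),
        widths=(0.06, 0.03),
    ),
}


def default_grid(n: int = 100) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def generate_inputs(
    grid: np.ndarray | None = None,
    specs: Mapping[str, ProfileSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> SpatialField:
    """Generate the BCD / TLL / maternal-HB input field.

    Deterministic under ``seed``; with ``noise=None`` the exact generating
    functions are returned.  Noisy values are clipped at zero and carry the
    generating sd.
    """
    x = default_grid() if grid is None else np.asarray(grid, dtype=float)
    use = dict(DEFAULT_INPUT_SPECS)
    if specs:
        use.update(specs)
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(use):
        mean = use[name].evaluate(x)
        if noise is None:
            out[name] = SpatialProfile(x, mean)
        else:
            sd = noise.sd(mean)
            vals = np.clip(mean + rng.normal(0.0, 1.0, len(x)) * sd, 0.0, None)
            out[name] = SpatialProfile(x, vals, sd)
    return SpatialField(out)


# -- ground-truth scenario ------------------------------------------------

#: Generating ("truth") rate constants for the synthetic calibration study.
#: Binding/unbinding rates stay at the compiler defaults; production,
#: degradation and repression strengths are set so the forward model turns
#: the smooth input gradients into an anterior HB domain and a posterior
#: KNI stripe, the qualitative cycle-14 geometry.
TRUTH_PARAMETERS: dict[str, float] = {
    # hb operon: BCD activation, KNI repression
    "kb_HB_KNI": 8.0,
    "kp_HB_a1r0": 3.0,
    "kp_HB_a1r1": 0.15,
    # kni operon: BCD activation, HB & TLL repression
    "kb_KNI_HB": 20.0,
    "kb_KNI_TLL": 20.0,
    "kp_KNI_a1r00": 6.0,
    "kp_KNI_a1r10": 0.05,
    "kp_KNI_a1r01": 0.05,
    "kp_KNI_a1r11": 0.02,
    # protein turnover
    "kd_HB": 0.8,
    "kd_KNI": 0.8,
}

TRUTH_GENE_TOTALS: dict[str, float] = {"HB": 1.0, "KNI": 1.0}

#: integration time of the out-of-equilibrium readout (time units)
TRUTH_T: float = 8.0


def truth_model() -> GapGeneModel:
    return build_gapgene_model(TRUTH_PARAMETERS, TRUTH_GENE_TOTALS)


def generate_ground_truth(
    parameters: Mapping[str, float] | None = None,
    gene_totals: Mapping[str, float] | None = None,
    grid: np.ndarray | None = None,
    T: float | None = None,
    noise: NoiseSpec | None = NoiseSpec(),
    seed: int = 0,
    n_steps: int = 600,
) -> tuple[SpatialField, dict]:
    """Forward-simulate known parameters and attach measurement noise.

    Returns ``(observed, truth)``: ``observed`` holds noisy HB and KNI
    profiles with per-point sd; ``truth`` records the generating
    parameters, inputs, noise-free predictions and readout time for
    recovery tests.
    """
    params = dict(TRUTH_PARAMETERS) if parameters is None else dict(parameters)
    totals = dict(TRUTH_GENE_TOTALS) if gene_totals is None else dict(gene_totals)
    Tval = TRUTH_T if T is None else float(T)
    x = default_grid() if grid is None else np.asarray(grid, dtype=float)

    inputs = generate_inputs(grid=x, noise=None, seed=seed)
    model = build_gapgene_model(params, totals)
    clean = predict_profiles(model, inputs, Tval, n_steps=n_steps)

    rng = np.random.default_rng(seed + 1)
    observed = {}
    for name in ("HB", "KNI"):
        mean = clean[name].values
        if noise is None:
            sd = np.full(len(x), 1.0)
            observed[name] = SpatialProfile(x, mean.copy(), sd)
        else:
            sd = noise.sd(mean)
            vals = np.clip(mean + rng.normal(0.0, 1.0, len(x)) * sd, 0.0, None)
            observed[name] = SpatialProfile(x, vals, sd)

    truth = {
        "parameters": params,
        "gene_totals": totals,
        "T": Tval,
        "inputs": inputs,
        "clean": clean,
        "seed": seed,
    }
    return SpatialField(observed), truth


#: Parameters exposed to the synthetic recovery study (production rates,
#: repression binding strengths, turnover, and the readout time ``T``).
#: The remaining rates stay at the compiler defaults, matching how the
#: truth scenario was generated.
FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "kp_HB_a1r0": (1e-2, 30.0),
    "kp_HB_a1r1": (1e-2, 30.0),
    "kp_KNI_a1r00": (1e-2, 30.0),
    "kp_KNI_a1r10": (1e-2, 30.0),
    "kp_KNI_a1r01": (1e-2, 30.0),
    "kp_KNI_a1r11": (1e-2, 30.0),
    "kb_HB_KNI": (1e-1, 30.0),
    "kb_KNI_HB": (1e-1, 30.0),
    "kb_KNI_TLL": (1e-1, 30.0),
    "kd_HB": (1e-2, 10.0),
    "kd_KNI": (1e-2, 10.0),
    "T": (1.0, 20.0),
}


def gapgene_fit_problem(
    observed: SpatialField,
    inputs: SpatialField,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    masks: Mapping[str, np.ndarray] | None = None,
    n_steps: int = 400,
):
    """Build a :class:`~grncompiler.calibration.FitProblem` for the
    synthetic gap-gene study.

    Bound keys are rate constants of the compiled model, plus optionally
    ``T`` (the out-of-equilibrium readout time) and ``total_HB`` /
    ``total_KNI`` (conserved gene totals).  The problem carries a
    vectorized population scorer: since a uniform time rescaling is
    equivalent to scaling every rate constant, candidates with different
    ``T`` integrate on one shared fixed-step grid with their rates scaled
    by ``T / T_ref``, so a whole GA population evaluates as a single
    batched RK4 sweep over (individual, position) columns.
    """
    from .calibration import FitProblem

    use_bounds = dict(FIT_BOUNDS) if bounds is None else dict(bounds)
    fit_T = "T" in use_bounds

    def split(params: Mapping[str, float]):
        rates = {k: v for k, v in params.items()
                 if k not in ("T", "total_HB", "total_KNI")}
        T = params.get("T", TRUTH_T)
        totals = {
            "HB": params.get("total_HB", TRUTH_GENE_TOTALS["HB"]),
            "KNI": params.get("total_KNI", TRUTH_GENE_TOTALS["KNI"]),
        }
        return rates, T, totals

    def predict(params: Mapping[str, float]) -> SpatialField:
        rates, T, totals = split(params)
        model = build_gapgene_model(rates, totals)
        with np.errstate(over="ignore", invalid="ignore"):
            return predict_profiles(model, inputs, T, n_steps=n_steps)

    batch = _make_batch_objective(observed, inputs, masks, split, n_steps)
    return FitProblem(predict, observed, use_bounds, masks,
                      objective_batch=batch)


def _make_batch_objective(observed, inputs, masks, split, n_steps):
    """Vectorized GA population scorer for the gap-gene model."""
    model0 = build_gapgene_model()
    ode = model0.odesys
    pos = inputs.positions
    m = len(pos)
    gamma = ode.stoich_matrix.astype(float)
    n_state = ode.n_state
    cprofiles = {s: inputs[s].values for s in ode.constant_species}
    i_hb = ode.species_index("HB")
    i_kni = ode.species_index("KNI")
    i_hb_free = ode.species_index(model0.free_state_names["HB"])
    i_kni_free = ode.species_index(model0.free_state_names["KNI"])
    maternal = inputs["HB_maternal"].values

    obs = {s: observed[s].values for s in observed}
    sds = {s: observed[s].sd for s in observed}
    use_masks = {
        s: (np.ones(m, dtype=bool) if masks is None or s not in masks
            else np.asarray(masks[s], dtype=bool))
        for s in observed
    }

    flux_meta = []
    for f in ode.fluxes:
        cfac = np.ones(m)
        for name, power in getattr(f, "_constant_powers", ()):
            cfac = cfac * cprofiles[name] ** power
        flux_meta.append((f.rate_name, f.rate_value, f.state_powers, cfac))

    T_ref = TRUTH_T

    def objective_batch(params_list):
        n_ind = len(params_list)
        ncol = n_ind * m
        pref = np.empty((len(flux_meta), n_ind, m))
        x0 = np.zeros((n_state, n_ind, m))
        for k, params in enumerate(params_list):
            rates, T, totals = split(params)
            scale = T / T_ref
            for j, (name, default, _, cfac) in enumerate(flux_meta):
                pref[j, k] = rates.get(name, default) * scale * cfac
            x0[i_hb_free, k] = totals["HB"]
            x0[i_kni_free, k] = totals["KNI"]
            x0[i_hb, k] = maternal
        # single precision: the objective is a chi-square over noisy data,
        # far above float32 resolution, and the integrator sweep is
        # memory-bandwidth bound
        pref = pref.reshape(len(flux_meta), ncol).astype(np.float32)
        x = x0.reshape(n_state, ncol).astype(np.float32)

        # every flux is at most bimolecular with unit exponents, so the
        # monomials reduce to two gathered factors (row n_state = ones)
        idx1 = np.full(len(flux_meta), n_state)
        idx2 = np.full(len(flux_meta), n_state)
        for j, (_, _, powers, _) in enumerate(flux_meta):
            flat = [i for i, p in powers for _ in range(p)]
            assert len(flat) <= 2
            if len(flat) > 0:
                idx1[j] = flat[0]
            if len(flat) > 1:
                idx2[j] = flat[1]
        gamma32 = np.ascontiguousarray(gamma, dtype=np.float32)
        nf = len(flux_meta)
        yext = np.ones((n_state + 1, ncol), dtype=np.float32)
        v = np.empty((nf, ncol), dtype=np.float32)
        fbuf = np.empty((nf, ncol), dtype=np.float32)
        stage = np.empty_like(x)
        ks = [np.empty_like(x) for _ in range(4)]

        def rhs(y, out):
            yext[:n_state] = y
            np.take(yext, idx1, axis=0, out=v)
            np.take(yext, idx2, axis=0, out=fbuf)
            np.multiply(v, fbuf, out=v)
            np.multiply(v, pref, out=v)
            np.matmul(gamma32, v, out=out)

        h = np.float32(T_ref / n_steps)
        half, sixth = np.float32(0.5), np.float32(1.0 / 6.0)
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(n_steps):
                rhs(x, ks[0])
                np.multiply(ks[0], half * h, out=stage)
                stage += x
                np.clip(stage, 0.0, None, out=stage)
                rhs(stage, ks[1])
                np.multiply(ks[1], half * h, out=stage)
                stage += x
                np.clip(stage, 0.0, None, out=stage)
                rhs(stage, ks[2])
                np.multiply(ks[2], h, out=stage)
                stage += x
                np.clip(stage, 0.0, None, out=stage)
                rhs(stage, ks[3])
                ks[1] += ks[2]
                ks[1] *= 2
                ks[1] += ks[0]
                ks[1] += ks[3]
                ks[1] *= sixth * h
                x += ks[1]
                np.clip(x, 0.0, None, out=x)
            x = x.astype(np.float64).reshape(n_state, n_ind, m)
            out = np.zeros(n_ind)
            for s, row in (("HB", i_hb), ("KNI", i_kni)):
                msk = use_masks[s]
                resid = (x[row][:, msk] - obs[s][msk]) / sds[s][msk]
                out += np.sum(resid**2, axis=1)
        return np.where(np.isfinite(out), out, np.inf)

    return objective_batch
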