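# Methods

## Model construction

A regulatory network is given as a *double graph*: one vertex set with an
ordered set of activation edges and an ordered set of repression edges.
Each ordered pair `(P, G)` says that protein `P` regulates transcription of
gene `G`. Vertex roles are inferred from connectivity: a vertex with
incoming regulation edges stands for a gene together with its protein; a
vertex with only outgoing edges is a pure transcription-factor input.
Vertices annotated `is_mrna` (maternal transcripts) are bookkeeping only:
their translation is folded into initial protein concentrations and they
contribute neither species nor reactions. Vertices annotated
`constant_input` are held at a fixed concentration and excluded from the
state.

Regulation follows the operon picture: transcription factors act only by
occupying binding sites on the gene. Two semantics are compiled:

- **per_site** — every incoming edge owns a site; a gene with `a`
  activators and `r` repressors has `2^(a+r)` occupancy states. Each state
  with at least one activator bound produces protein at its own rate
  (including states that also carry bound repressors — their rates are free
  parameters, typically calibrated small).
- **one_site** — all regulators compete for one site; `a+r+1` states; only
  activator-bound states produce.

A gene with no incoming activation edges produces at a basal rate from
repressor-free states; otherwise unbound genes are silent. Proteins decay
by first-order degradation; operon states are perfect catalysts (never
degrade, never consumed), and a regulator bound to DNA is sequestered and
does not degrade until it unbinds. The compiled network contains only
unimolecular and bimolecular elementary reactions.

## Rate equations and conservation laws

Mass action gives `dX/dt = Γ v(X)` with flux monomials
`v_j = k_j ∏ X_i^{α_ij}` and integer stoichiometric matrix `Γ` over the
state species (constant inputs enter fluxes as numbers). Conservation laws
are the left null space of `Γ`, computed over the rationals (sympy
nullspace of `Γᵀ`), scaled to coprime integers with positive leading
entry, and ordered by pivot column, so the basis is bit-stable across
runs. Because operon states are catalysts, each gene contributes exactly
one law: its total operon concentration.

`reduce_by_conservation` eliminates one chosen species per law. The
reduced vector field is evaluated by exact affine reconstruction of the
eliminated coordinates (the Jacobian uses the chain rule through that
reconstruction); the symbolic view performs the literal substitution and
both representations are asserted equal in the tests.

## Dynamics and the threshold

Trajectories use LSODA (rtol 1e-9, atol 1e-12 by default) with the
analytic polynomial Jacobian; a fixed-step RK4 companion handles large
batched runs and is checked against the adaptive solver (< 1e-6 on the
reference fixtures). Steady states are located by multistart damped
root-finding (default 50 log-uniform starts plus the origin), deduplicated
at 1e-8, and classified by the Jacobian spectrum with a 1e-9 margin for
"marginal".

For a self-activating gene the conserved operon total `C` is a bifurcation
parameter. On the reduced system

    db/dt = k_b A (C - b) - k_u b
    dA/dt = -k_b A (C - b) + (k_u + k_p) b - k_d A

the quiescent branch `(0, 0)` has Jacobian determinant
`k_u k_d - k_b k_p C`, so it loses stability at

    C* = k_u k_d / (k_b k_p),

where the positive branch `b* = C - C*`, `A* = k_p b*/k_d` emerges — a
transcritical exchange. `threshold_scan` tracks the quiescent branch and
locates `C*` by bisection on its leading eigenvalue (relative tolerance
1e-6); the tests also re-derive `C*` symbolically and compare.

## Spatial patterning without transport

Space enters only through position-dependent constant-regulator profiles
and initial conditions on a scaled axis `x ∈ [0, 1]` (default grid 100
points); every position integrates independently — no diffusion or
advection. When all regulators are constant the kinetics are affine-linear
and the per-position steady state is solved exactly after substituting the
gene-total conservation law; for the one-activator/two-repressor
competitive motif this closed form is

    C_ss(x) = (p/d) · C_tot · (aA/a') / (1 + aA/a' + r₁R₁/r₁' + r₂R₂/r₂'),

with `a, a'` (etc.) the binding/unbinding rates evaluated at the local
regulator concentrations. Flanking repressor bumps around a flat activator
therefore carve a single interior expression spike, in either semantics.

## The gap-gene model

The cross-regulation network (BCD activates hb and kni; HB and KNI
mutually repress; TLL represses kni) compiled per-site gives 4 hb-operon
states, 8 kni-operon states and the proteins HB and KNI: 14 equations per
position with two gene-total conservation laws. BCD and TLL are constant
spatial inputs; maternal HB is an initial condition; KNI starts at zero;
operons start fully free at the gene-total concentration (the natural
pre-transcription state — the occupancy split is not observable at t=0).
Profiles are read out at a finite time `T`, not at steady state. Since a
uniform time rescaling is equivalent to scaling every rate constant,
fitting `T` is implemented by a global rate scale on a fixed integration
grid; the identity is asserted in the tests.

## Synthetic profiles

The generator emulates quantified anterior-posterior protein profiles:
exponential BCD (amplitude 4, decay length 0.2), sigmoidal maternal HB
(amplitude 2, center 0.45, width 0.05), posterior Gaussian TLL (amplitude
3 at 0.88, width 0.06, small anterior shoulder), all in arbitrary
concentration units on `x ∈ [0, 1]`. Measurement noise is Gaussian with
`sd = 0.02 + 0.05·value`, clipped at zero (the clip slightly truncates the
noise distribution near zero concentrations). Ground-truth rate constants
(`TRUTH_PARAMETERS`) keep binding/unbinding at the compiler defaults and
set production, repression-binding and degradation rates so the forward
model yields an anterior HB domain and a single posterior KNI stripe at
readout `T = 8`.

What the generator does *not* emulate: embryo-to-embryo variability and
registration, background subtraction, nuclear discreteness, and any
regulators beyond the four modeled species — so passing recovery tests
demonstrate that the calibration machinery works on data of this
smoothness and noise level, not that the biological network is identified
from real embryos.

## Calibration

The objective is a sum of masked chi-squares
`Σ ((pred - obs)/sd)²` over fitted species, with reduced (penalized)
chi-square reported as `χ²/(N - p)`; when data carry no sd a floor of
`max(ε, 5% of the species maximum)` would apply (the synthetic generator
always attaches sd). Optimization is a generational genetic algorithm on
log10 parameters within positive bounds: tournament selection (size 4),
blend crossover, a differential-recombination operator (child = parent +
F·(pop_i - pop_j), F ∈ [0.4, 0.9]) that follows the valley directions of
this sloppy objective, Gaussian mutation whose per-offspring scale is
drawn log-uniformly between 0.005 and 0.5 decades (coarse exploration plus
fine refinement), and 2 elites. Runs are deterministic under a fixed seed;
failed integrations score +inf. Populations are scored in one vectorized
single-precision RK4 sweep over (individual × position) columns.

The synthetic recovery study fits 12 parameters (6 production rates, 3
repression binding rates, 2 degradation rates, and `T`) on a 50-position
grid with a 200-step time grid. Only objective-level recovery is asserted
(best objective within 1.2× of the generating parameters' objective): the
model is sloppy and parameter-wise identifiability is not claimed.

## Numerical choices and limitations

- Exact rational null spaces make conservation laws deterministic;
  floating SVD rank is used only as an independent test oracle.
- Concentrations are clipped at zero inside fixed-step integrators; the
  adaptive solver relies on tight tolerances instead.
- The fixed-step batch integrator is appropriate for the non-stiff rate
  regimes of the calibration bounds; grossly stiff candidates overflow and
  are scored +inf, which simply removes them from the GA population.
- Steady-state search is heuristic multistart: completeness of the root
  list is only guaranteed for the small fixture systems where the root
  structure is known analytically.
- Hill-function / quasi-steady-state reductions, stochastic kinetics, and
  transport (diffusion/advection) terms are out of scope by design.
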