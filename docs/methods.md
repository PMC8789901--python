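# Methods

## Model and assumptions

The AVM body is a one-dimensional porous medium on `[0, L]` through which
blood (displaced phase, saturation `S ∈ [0,1]`) and the embolic agent
(displacing phase, `1−S`) filter jointly.  Both fluids are Newtonian,
incompressible and immiscible; capillary forces, agent adsorption, wall
deformation/permeability and agent hardening are neglected, as is the
cardiac-cycle pulsatility (embolization is much longer than one beat).
Mass conservation of blood gives the scalar conservation law

    (m A S)_t + (Q f(S))_x = 0,

nondivergent form `S_t + (Q/(mA)) f(S)_x = 0`, with `Q(t)` independent of
`x` (impermeable walls, incompressible phases).  The fractional flow is
the mobility ratio

    f(S) = (k_b(S)/η_b) / (k_b(S)/η_b + k_e(1−S)/η_e),
    k_b(S) = S^α_b,  k_e(ξ) = ξ^α_e,

which satisfies `f(0)=0`, `f(1)=1`, `f′>0`, and is convex below a single
inflection and concave above it for the clinical viscosities
(`η_b = 4 cP`, `η_e = 18 cP`) and exponents ≥ 1.  The blood-phase
exponents `α_b` come from the per-patient filtration tables; the
embolic-phase exponent `α_e` is not tabulated anywhere, so it is a free
model parameter here, default `α_e = 2` (quadratic), which produces the
required S-shape against every tabulated `α_b`.

The healthy vascular bed surrounding the AVM enters through two response
curves of the mean saturation `S̄(t) = (1/L)∫S dx`:

* `q̄_b(S̄)` — blood inflow into the AVM (cm³/s), strictly positive so the
  mixture flow `Q = q_e + q̄_b` never vanishes and all characteristics run
  inlet → outlet (hence one boundary condition at `x = 0` only);
* `p₂(S̄)` — outlet pressure (mmHg).

The inlet pressure follows from Darcy's law,

    p₁(t) = p₂(S̄) + Q(t) ∫₀ᴸ η_b f(S) / (A(x) K k_b(S)) dx,

evaluated in mmHg (1 mmHg = 1333.22 dyn/cm²; all other units are CGS).
The integrand `f/k_b` has a finite limit as `S → 0` (because `f` vanishes
at least as fast as `k_b`); it is evaluated with a floor `S ≥ 1e−12` to
avoid 0/0 in fully embolized cells.

The inlet boundary condition is integral: `f(S(t,0)) = q̄_b(S̄)/(q_e+q̄_b)`,
coupling the boundary value to the instantaneous spatial mean.

### Controls

Each stage `i` injects `q_e(t) = γᵢ Qᵢ(Tᵢ₋₁) Eᵢ(t)` with the trapezoid
envelope `Eᵢ`: linear ramp-up over `θ₁ᵢ`, plateau `θ₂ᵢ`, linear ramp-down
over the fixed `ε`.  `ε = 0.1 s` is a constant of the procedure (the
clinical practice of stopping the supply quickly), never an optimization
variable.  Below `θ₁ = 1e−8 s` the continuous envelope degenerates
numerically and the discontinuous ("bang") variant is used: `E = 0` at
the stage-start instant exactly, 1 immediately after.  `Qᵢ(Tᵢ₋₁)` is the
mixture flow frozen at the stage start; since `q_e` vanishes there it
equals `q̄_b` at the stage-initial mean.

### Multi-stage chaining

Between stages the agent solidifies where it sits; with zero-duration
breaks the next stage's lumen is `Aᵢ(x) = Aᵢ₋₁(x) Sᵢ₋₁(Tᵢ₋₁, x)` nodewise
(floored at `1e−6·A₁` to keep `1/(mAᵢ)` finite), each stage restarts from
pure blood `Sᵢ = 1` on the reduced lumen, and the filtration
characteristics (`m`, `K`, `k_b`, `f`) are assumed unchanged from stage to
stage.  The blood fraction of the *original* lumen, `Ψᵢ = Sᵢ Aᵢ/A₁`, is
continuous across breaks by construction; the objective is
`J_N = (1/L)∫ Ψ_N(T_N, x) dx ∈ [0,1]` (0 = fully embolized).  Two safety
constraints per stage: `Sᵢ(t, L) = 1` (no agent in the vein; in floating
point, the recorded outlet value must stay above `1 − 1e−6` — the front's
arrival produces an O(1) drop, so any tolerance far below that amplitude
works) and `max p₁ ≤ p*`.  Violations set unit indicators `I₁, I₂` and the
optimizer minimizes `Ĵ_N = J_N + R Σᵢ(I₁ᵢ + I₂ᵢ)` with `R = 1000`.

## Numerical scheme

A two-layer CABARET scheme on a uniform grid of `J` cells advances flux
variables `u_j` (integer nodes) and conservative variables `U_{j+1/2}`
(half-integer nodes), both initialized to 1 at each stage start.  One step:

1. time step `τ` (below);
2. layer-n mixture flow `Qⁿ = q_e(tⁿ) + q̄_b(V̄ⁿ)` and inlet pressure by
   the midpoint-rule Darcy quadrature over `V = U·Aᵢ/A₁`;
3. conservative half-step `U^{n+1/2} = Uⁿ − (τ/2)·Qⁿ/(mAᵢ)·Δf(uⁿ)/h`;
4. half-layer fluxes: the inlet flux from the integral boundary condition,
   `f₀^{n+1/2} = q̄_b(V̄^{n+1/2}) / (q_e(tⁿ) + q̄_b(V̄^{n+1/2}))` — note
   `q_e` deliberately at the layer-n time while `V̄` is at the half layer —
   and interior fluxes `f_j^{n+1/2}` from the extrapolation
   `ū_j = 2U_{j−1/2}^{n+1/2} − u_{j−1}ⁿ` averaged with `u_jⁿ`, limited
   two-sidedly into the bracket of `(f(U_{j−1/2}ⁿ), f(u_jⁿ))`, then
   corrected for local monotonicity (below);
5. half-layer flow `Q^{n+1/2}` (same formula at `t^{n+1/2}`);
6. conservative full step with `Q^{n+1/2}` and the half-layer fluxes;
7. flux variables: `u₀^{n+1} = f⁻¹(f₀^{n+1})` with the boundary flux
   evaluated on `U^{n+1}` and `q_e(t^{n+1})`; interior
   `ũ_j = 2f⁻¹(f_j^{n+1/2}) − u_jⁿ` limited into the bracket of the two
   neighbouring `U^{n+1}`; the outflow node `u_J` limited by its single
   interior neighbour `U_{J−1/2}^{n+1}` together with its own previous
   value (no downstream neighbour exists; all characteristics leave
   rightward, and this choice preserves the scheme's exactness on
   monotone data).

### Additional monotonicity correction

Two-sided limiting alone does not prevent oscillations at shocks.  Where
the layer-n four-point flux sequence
`f(U_{k−3/2}), f(u_{k−1}), f(U_{k−1/2}), f(u_k)` is nondecreasing
(checked first; non-strict comparisons, so constant states satisfy both
branches harmlessly) the candidate flux is capped above by

    f(u_{k−1}ⁿ) + φ_{k−1}ⁿ,   φ_{k−1}ⁿ = A(x_{k−1}) m(x_{k−1})
                                  (U_{k−1/2}ⁿ − u_{k−1}ⁿ) / (rⁿ Qⁿ),

with `rⁿ = τⁿ/h`; on nonincreasing sequences the same expression floors it
from below (`φ` is then nonpositive).  This is the discrete local maximum
principle bound of the monotone-CABARET construction; for linear advection
at Courant number 1 it is tight with *equality*, so the scheme's exact
translation property survives the correction.  The correction applies for
`k ≥ 2` only (the `k−3/2` stencil value must exist); at `k = 1` and the
boundaries only the two-sided limiter acts.

### Time step

The nominal step is `τ = r·h / max_j a(U_{j+1/2})`, `a = Q f′(S)/(mA)`,
with CFL number `r = 0.5` by default.  Two strengthenings make this robust
for this problem:

* **State-range speed bound.**  At every stage start `S ≡ 1` while
  `f′(1) = 0` (for `α_e > 1`), so the pointwise maximum vanishes although
  the inlet is about to launch a shock with finite Rankine–Hugoniot speed.
  Since every shock speed between states in `[S_min, S_max]` is a mean
  value of `f′` over that range, the solver bounds all signal speeds by
  the grid maximum of `f′` over the range spanned by the current fields
  *and* the inlet value the boundary condition implies — evaluated twice,
  once with the current inflow and once with the inflow anticipated at the
  end of the tentative step (otherwise an initial zero-speed state would
  leap over the whole ramp-up).
* **Breakpoint clipping.**  Steps are clipped to land exactly on the
  control breakpoints (`θ₁ᵢ`, start of ramp-down, stage end), so the
  constraint functionals sample every kink of the control and the terminal
  time is hit exactly.  Constraints are evaluated on the recorded per-step
  values only, with no dense interpolation.

The inverse fractional flow (needed at every node each step) is a
vectorized Newton iteration safeguarded by bisection on `[0,1]`,
terminating when the residual is ≤ 1e−12 *and* the Newton step is ≤ 1e−13
(the residual alone is weak where `f′` vanishes at the endpoints).

A compiled (numba) replica of the stage loop handles the parametric
synthetic-model family; it is pinned to the numpy reference implementation
by tests (terminal fields within 1e−10, identical step counts and
penalties) and exists purely for speed at optimization scale.

## Optimizer

Particles live in the nonnegative orthant of `R^{3N}` with stage-major
coordinates `(γ₁, θ₁₁, θ₂₁, …)`.  The box `[0,b]` (defaults: 30 for `γ`,
10 s for `θ` coordinates — the problem itself only requires nonnegativity,
but the subdomain sampling needs a bounded region; iterates may leave the
box upward) is sliced into `M` equal half-open slabs along the first
coordinate; one particle starts uniformly in each slab.  Updates use the
inertia schedule `wᵏ = w₁ − w₂k/I` with `w₁ = 0.9`, `w₂ = 0.5`,
`c₁ = c₂ = 1.49`; the stochastic factors `r₁, r₂` are drawn per coordinate
by default (the common convention, better exploration; a config flag
restores per-particle scalars).  Negative proposed coordinates are set to
zero and the velocity is recomputed as the realized displacement.
Personal bests are replaced only on strict improvement; the global best is
the argmin of personal bests (first index on ties), hence non-increasing.
After bookkeeping, each particle independently returns to a uniform point
of its *own* original subdomain with probability `P = 0.15` (velocity
zeroed).  Iterations: `I = 300`; particles: `M = 16` for two-stage plans,
32 for three-stage.  All randomness flows from a single seeded generator;
the CLI derives named child streams (swarm, patient generation) from the
config seed so features do not perturb each other's draws.

## Synthetic patients

Three clinical geometry/filtration rows are built in (L, A, K, α_b, p*
for patients K, S, P), with `m = 1` (other constants rescale time) and
constant cross-section.  The true healthy-bed response curves are
unpublished patient-specific interpolants of intraoperative measurements;
the generator substitutes smooth monotone stand-ins

    q̄_b(S̄) = q_base (q_floor + (1 − q_floor) S̄^q_shape),
    p₂(S̄)  = p_out_base − p_out_drop (1 − S̄),

defaults `q_base = 1 cm³/s`, `q_floor = 0.2`, `q_shape = 2`,
`p_out_base = 30 mmHg`, `p_out_drop = 5 mmHg`.  The defaults keep the
no-injection Darcy state feasible for every fixture (for patient K the
margin is small — baseline 73.1 vs critical 80.7 mmHg — so the pressure
constraint genuinely binds under injection).  `random_patient` draws
valid models bracketing the clinical magnitudes, optionally with smoothly
varying `A(x)` and `m(x)` (these use the reference solver path).  What
passing tests show is therefore fidelity of the *solver and optimizer* to
this model family, not fidelity of the stand-in curves to any real
patient's bed response; per-patient optima depend strongly on those
curves and are not comparable to clinical tables.

## Verification oracles and problem sizes

* Linear advection, `f(S) = S`, `Q = m = A = 1`, Courant number 1, J=100:
  node-exact translation (≤ 1e−12 per step over 200 steps).  Exactness
  through the inlet requires injecting the profile in the scheme's
  staggered representation: the half-layer inlet value is the average of
  consecutive node samples, which a pointwise sample matches only to
  O(h²); `run_prescribed` exposes an `inflow_half` hook for this.
* Buckley–Leverett Riemann problem (inlet 0 displacing 1, constant Q) vs
  an independently implemented Welge tangent construction: tangent point
  from `f′(S*)(1−S*) = 1−f(S*)` by bracketed root finding, rarefaction by
  inverting `f′` below `S*`, tangential shock at `v f′(S*) t`.  Measured:
  first-order L1 convergence (error ratio ≥ 1.5 between J=100 and J=200)
  and ≤ 2% shock-position error at J=200.
* Total variation of `u` non-increasing (tolerance 1e−10) and all fields
  in `[0,1]` at every step of the Riemann runs.
* Sphere recovery in `R⁶` (box `[0,5]⁶`, interior target) with the study
  swarm constants (M=16, I=300): best value ≤ 1e−3 for five consecutive
  seeds.  Note that the nonnegativity clipping makes `x_l = 0` an
  absorbing state for a coordinate once the personal and global bests
  collapse onto it; for targets very close to the boundary this can trap
  a run, so verification targets sit clearly inside the box.  In the
  control problem the analogous behaviour is benign (a zero `γ` or `θ` is
  a meaningful bang/degenerate control, and reinitialization keeps
  sampling the interior).
* End-to-end seeded optimization at desk scale: fixture S, two stages,
  M=8, I=40, J=40, bounds γ ≤ 8, θ ≤ 4 s — a configuration chosen so the
  search spans feasible and infeasible regions while a full run completes
  in well under a minute per seed; the optimum must be penalty-free and
  beat both the no-injection state and a fixed feasible reference plan.

## Known limitations

* One compartment, one spatial dimension; no multi-compartment AVMs.
* No agent-viscosity hardening; viscosities constant.
* The inverse problem (reconstructing `f`, `k_b`, `q̄_b`, `p₂` from
  intraoperative recordings) is out of scope; response curves are either
  synthetic or user-supplied callables.
* Free-form (non-trapezoid) controls are not represented.
* The scheme is explicit; strongly embolized stages (tiny `Aᵢ`) shrink the
  stable step, bounded below by the lumen floor and the step cap.
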