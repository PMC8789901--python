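# emboflow

Simulation and optimal control of multi-stage endovascular embolization of
a cerebral arteriovenous malformation (AVM).

An AVM is a congenital tangle of vessels connecting the arterial and venous
pools directly, bypassing the capillaries.  The standard treatment —
embolization — fills the abnormal vessels with a viscous embolic agent
(e.g. ONYX18) injected through a catheter at the arterial inlet, usually in
several stages.  The clinical tension is between *effectiveness* (displace
as much blood as possible) and *safety* (the agent must not reach the
venous outlet, and the inlet pressure must not rise above a critical
value).  `emboflow` is for researchers in computational hemodynamics who
want to study injection schedules on this model: it simulates one schedule,
or searches for an optimal one.

## Model

Blood (saturation `S`, the displaced phase) and the embolic agent
(saturation `1−S`) filter jointly through the one-dimensional AVM body
`x ∈ [0, L]` under Darcy's law:

    ∂(m A S)/∂t + ∂(Q f(S))/∂x = 0 ,

where `m(x)` is the porosity, `A(x)` the cross-section open to flow,
`Q(t)` the total mixture flow and `f(S)` the Buckley–Leverett fractional
flow — here the mobility ratio `f = (k_b/η_b) / (k_b/η_b + k_e/η_e)` with
power-law relative permeabilities, blood viscosity 4 cP and agent
viscosity 18 cP, giving the classical S-shaped flux with one inflection.
The surrounding healthy bed enters through two response curves of the mean
saturation `S̄`: the blood inflow `q̄_b(S̄) > 0` and the outlet pressure
`p₂(S̄)`, so that `Q(t) = q_e(t) + q̄_b(S̄(t))` and the inlet boundary value
satisfies the integral condition `f(S(t,0)) = q̄_b(S̄)/(q_e + q̄_b)`.  The
control `q_e(t)` is a per-stage trapezoid `γᵢ Qᵢ(Tᵢ₋₁) Eᵢ(t)` with ramp-up
`θ₁ᵢ`, plateau `θ₂ᵢ` and a fixed ramp-down `ε = 0.1 s`; the degenerate
`θ₁ᵢ = 0` case is the discontinuous "bang" profile.  Between stages the
agent solidifies and the lumen shrinks, `Aᵢ = Aᵢ₋₁ Sᵢ₋₁(Tᵢ₋₁)`.

The conservation law is integrated by a monotone CABARET scheme (staggered
flux/conservative variables, two-sided flux limiting plus an additional
local-monotonicity correction) that is exact for linear advection at
Courant numbers 0.5 and 1 and localizes the Buckley–Leverett shock
sharply.  The control problem minimizes the terminal mean blood fraction
`J_N = (1/L)∫ Ψ_N dx` (with `Ψᵢ = Sᵢ Aᵢ/A₁` the blood fraction of the
*original* lumen) subject to the two safety constraints, handled by unit
penalties weighted by `R = 1000`; the resulting box-constrained problem is
solved by a modified particle swarm (disjoint-subdomain initialization,
inertia schedule `wᵏ = w₁ − w₂ k/I`, nonnegativity clipping, probabilistic
reinitialization with `P = 0.15`).

Patient geometries for three clinical cases (fixtures `K`, `S`, `P`) are
built in; the healthy-bed response curves are synthetic monotone stand-ins
with the qualitative shape of the clinical interpolants.

## Worked example

Simulate a single-stage injection on patient `S` (γ=1, ramp-up 1 s,
plateau 2 s):

```python
import emboflow as ef

model = ef.patient_fixture("S")
ff = ef.build_fractional_flow(model)
grid = ef.Grid1D(J=100, L=model.L)
plan = ef.ControlPlan([ef.StageControl(gamma=1.0, theta1=1.0, theta2=2.0)])
ev = ef.simulate_plan(model, ff, plan, grid, r=0.5)
tr = ev.traces[0]
print(f"J_N      = {ev.J_N:.4f}")
print(f"J_hat    = {ev.J_hat:.4f}")
print(f"penalty  = {ev.penalties}")
print(f"max p1   = {tr.p1.max():.1f} mmHg  (p* = {model.p_star})")
print(f"min S(L) = {tr.S_outlet.min():.6f}")
```

prints

```
J_N      = 0.3600
J_hat    = 0.3600
penalty  = [(0, 0)]
max p1   = 63.4 mmHg  (p* = 114.6)
min S(L) = 1.000000
```

i.e. after 3.1 s of injection 64% of the original lumen is embolized
(`J_N = 0.36`), no agent reached the vein (`S(L)` never left 1), the inlet
pressure peaked at 63.4 mmHg — below the critical 114.6 mmHg — so both
safety indicators stayed 0 and the penalized objective equals `J_N`.

The same runs from a shell:

```bash
emboflow make-patient --fixture S -o patient.yaml
emboflow simulate -c config.yaml       # plan given in the config
emboflow optimize -c config.yaml       # particle-swarm search
```

with the grid (`grid_J: 100`), CFL number (`cfl: 0.5`), plan or swarm
settings, output directory and seed all in one YAML config.  Outputs are
per-stage CSV traces `(t, tau, Q, p1, Sbar, S_outlet)`, terminal-field
CSVs and a JSON summary; optimization additionally writes the best plan
and the per-iteration best-value history.

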