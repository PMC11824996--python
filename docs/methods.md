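# Methods

## Model and conventions

The state is `(T, E, N, S, M)`: tumor cells, effector-immune cells,
normal cells, stem cells, and the amount of chemotherapeutic agent.
Dynamics are Caputo-fractional of order `α ∈ (0, 1]`; `α = 1` recovers
the classical system and is the regime in which the model's reference
equilibrium values live. Memory enters only through the derivative: the
vector field itself is autonomous apart from the infusion `v(t)`.

**α-scaling.** Every first-order rate constant enters the dynamics as
`rate^α`, the usual dimensional-consistency convention for
fractionalized compartment models. We apply the convention uniformly —
including the reciprocal carrying capacities `b1`, `b2` — so that the
closed-form equilibria are exact fixed points of the implemented vector
field at every order, not only at `α = 1` (the residual invariant
`‖f(x*)‖∞ < 1e-9` relative to state magnitude is enforced in the test
suite across orders). The infusion is the one exception: the dynamics
use raw `v(t)`, while steady-state formulas use the drug level
`M* = v^α/γ2^α`; the two conventions coincide at `α = 1`.

**Stem-cell sign.** The stem line is `stem_sign · γ1^α S − kS^α M S`.
The default `stem_sign = +1` takes the system as written (stem cells
grow exponentially in the absence of drug, and at baseline response
rates the drug cannot stop them — the `kS M* > γ1` sufficient condition
fails by ~0.1/day). With `stem_sign = −1`, `γ1` acts as the decay rate
its name suggests and the tumor-free point under steady drug acquires a
strictly negative real spectrum. Equilibria are unaffected: every
reported branch has `S* = 0`. We surface the switch rather than resolve
the ambiguity.

## Equilibria and fractional stability

Three branches, all with `S* = 0`:

* **tumor-free** `(0, ρ/(μ + p2 M*), 1/b2 − kN M*/(r2 b2), 0, M*)`
  (scaled rates throughout); exists iff the normal-cell component is
  positive, i.e. `r2^α > kN^α v^α/γ2^α`.
* **coexisting**: substituting the effector balance
  `E(T) = ρ/(μ + p2(T + M*))` into the tumor balance
  `r1(1 − b1 T) = p3 E(T) + kT M*` and clearing the denominator yields a
  quadratic in `T`; all real roots in `(0, 1/b1]` are returned with
  induced `E`, `N` and existence margins — no silent root selection.
* **dead** (`N = 0`): the same `(T, E)` fixed points with normal cells
  extinct, plus `(0, ρ/(μ + p2 M*))`. Reported for completeness, never
  used for treatment conclusions.

Stability is the Matignon condition: asymptotic stability iff every
Jacobian eigenvalue satisfies `|arg λ| > απ/2`. `classify_stability`
computes the dense 5×5 eigenvalues; a factored route (three explicit
diagonal eigenvalues plus the tumor-effector quadratic
`λ² + c1 λ + c2`, valid at `S* = 0`) is exposed as an independent
cross-check. The verdict margin `min|arg λ| − απ/2` is classified with a
1e-10-radian marginal band; a zero eigenvalue is reported marginal.

**Critical order — a caution.** `critical_alpha(c1, c2)` returns the
closed form `(2/π)·arctan(√(4c2 − c1²)/c1)` for a complex pair with
`c1 > 0` (and 1 at `c1 = 0`; absent for real roots or `c1 < 0`). For
`c1 > 0`, however, the pair `(−c1 ± i√(4c2 − c1²))/2` lies in the left
half plane with `|arg| = π − arctan(·) > π/2`, so the exact Matignon
test finds stability at *every* order in `(0, 1]`: the closed form is a
conservative threshold, not the true crossing. It coincides with the
genuine wedge-crossing order of the sign-mirrored right-half-plane pair
(`c1 → −c1`), and the test suite verifies exactly that relationship by
brute-force α-scan. Verdicts always come from the eigenvalue test,
never from the formula.

## Caputo solvers

* **ABM** (`abm_solve`): fractional Adams–Bashforth–Moulton
  predictor–corrector (PECE, one corrector pass by default) on the
  Volterra integral form; product-rectangle predictor,
  product-trapezoid corrector, full history. Exact for constant
  forcing; observed order ~1+α on the linear relaxation test.
* **L1 forward** (`l1_forward_solve`): implicit L1 discretization with
  weights `δ(j,n) = (n−j)^{1−α} − (n−j+1)^{1−α}` and a per-step Newton
  iteration (∞-norm tolerance 1e-10, max 25 iterations, previous node
  as initial iterate). At `α = 1` the history weights vanish
  identically and the scheme is backward Euler; for the five-state
  model that path is compiled with numba (equations kept in lock-step
  with `model.rhs`, asserted equal in the tests) so that fine classical
  grids are affordable.
* **L1 backward** (`l1_backward_solve`): the right-Caputo mirror with
  weights `ξ(m) = m^{1−α} − (m−1)^{1−α}`, marching from the zero
  terminal condition and solving one 5×5 linear system per node; for
  affine (adjoint-type) right-hand sides the step is exact linear
  algebra, no inner iteration. At `α = 1` it is implicit Euler run
  backward.

Both L1 schemes and ABM retain the full history: work is O(N²) in the
number of steps and no short-memory truncation is applied. Grids are
uniform only.

**Known scheme limitation.** The solution of the relaxation test
`D^α y = −y` behaves like `1 − t^α/Γ(1+α)` near `t = 0`; the plain
uniform-grid L1 scheme then carries a first-node error
`t1^α (1/Γ(1+α) − Γ(2−α))`, i.e. O(h^α) at the initial layer
(≈ 2.5e-3 at `h = 1e-3`, `α = 0.65`; ≈ 2.1e-4 at `α = 0.95`). This is
intrinsic to the discretization, not an implementation artifact; away
from the initial layer the error is much smaller, and the ABM scheme
does not share the limitation. The corresponding solver-accuracy test
asserts a uniform 1e-3 bound for both schemes and is expected to fail
for L1 at `α = 0.65`.

**Mittag–Leffler oracle.** `E_α(z)` by power series in arbitrary
precision (mpmath, guard digits scaled as `|z|^{1/α}` against
cancellation), switching to the algebraic asymptotic series below
`z = −30`; `E_1 = exp` exactly. Used only as an accuracy oracle, never
inside the schemes.

## Ulam–Hyers certificates

The quadratic field has no global Lipschitz constant, so κ is defined
over a user-stated compact box as the sup of the induced 1-norm of the
Jacobian (matching the sum-of-components state norm) on a deterministic
lattice — reproducible by construction. The column sums are affine in
each coordinate, so the sup over the box is attained at lattice
vertices; resolution 5 and 9 agree within 5% on the `[0, 10]⁵` box.
With `Ψ = T^α/Γ(α+1)` and `Ω = Ψκ`, `Ω < 1` certifies uniqueness and
Ulam–Hyers stability on `[0, T]`; the maximal certified horizon
`T* = (Γ(α+1)/κ)^{1/α}` is reported alongside. An affine growth bound
`‖f(H)‖₁ ≤ σ‖H‖₁ + τ` is fitted over the same lattice (σ = κ, τ the
smallest feasible intercept) with no tightness claim. At baseline rates
the drug-decay column makes κ ≈ 2 on `[0, 10]⁵`, so certified horizons
are short (fractions of a day) — the certificate is honest about being
a local statement.

## Optimal chemotherapy scheduling

Objective `J(v) = ∫₀^{tf} B1 T + ½ B2 v² dt` over measurable
`0 ≤ v ≤ 1`. The costates obey the right-Caputo system
`D^α_{t,tf} λ = ∂H/∂x` with `H = B1 T + ½B2 v² + λ·f` and `λ(tf) = 0`;
the adjoint right-hand side is generated from the implemented Jacobian
transpose (so it follows whatever `stem_sign` is active) rather than
transcribed, and is verified against central finite differences of the
scalar Hamiltonian. Stationarity gives `v* = clamp(−λ5/B2, 0, 1)`.

The forward–backward sweep alternates an L1 forward state solve (ABM
selectable), the backward costate solve, and a relaxed control update
`v ← (1−ω) v + ω clamp(−λ5/B2, 0, 1)` with ω = 0.5 by default (ω = 1 is
the plain update; the damping stabilizes the fixed-point iteration).
Convergence is declared when
`ψ = min_z [δ(‖z‖₁ + 1e-9) − ‖z − z_old‖₁] ≥ 0` over all five state
components, five costates and the control, with δ = 1e-3. The 1e-9
absolute floor is a numerical guard: a component that converges to
exactly zero (e.g. the control when `B1 = 0`) has a constant *relative*
change under damped iteration and would otherwise never satisfy the
rule; the floor is invisible for any component of nonzero size. A sweep
budget overrun returns the last iterate flagged non-converged, never
silently.

**Weights and scenario.** `B1 = B2 = 1` by default (the weights are
genuinely free parameters of the formulation; reproducibility reports
should state them). The control scenario uses a slowly cleared drug,
`γ2 = 0.1/day`. The full-fidelity window of 120 days at step 0.001
(120 000 nodes) is available as the `focp_full_grid` scenario but is
expensive under O(N²) kernels; the default study scenario is 50 days at
step 0.05 (1000 nodes), where the sweep converges in ~10 iterations and
reproduces the qualitative signatures: early full-strength dosing with
a taper to zero at the horizon, decaying end-of-treatment drug levels
versus monotone accumulation toward `v/γ2` under constant infusion, and
a lower terminal tumor burden than the untreated run.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale defaults: solver-accuracy
comparisons on `[0, 1]` with N = 1000 base grids and two halvings
(errors compared on shared nodes against the Mittag–Leffler closed
form); classical-limit agreement on `[0, 50]` with N = 5000 for ABM and
N = 2.5×10⁶ for the backward-Euler limit of L1 (first-order scheme, so
a fine grid is needed for 1e-5 relative agreement); ABM–L1
cross-consistency at α = 0.9 on `[0, 20]` with N = 4000; the
optimal-control scenario at its 1000-node default.

## What the scenarios do and do not show

The built-in scenarios are the model's own study conditions, not data:
no-chemotherapy (`v = 0, M0 = 0`), constant infusion `v = 0.5`, and the
optimized schedule, each over `α ∈ {0.65, 0.75, 0.85, 0.95}` from the
baseline initial state `(2, 0.1, 1, 0.5, 0.5)`. Passing tests certify
internal consistency (schemes agree with closed forms, with each other,
and with classical limits) and the model's qualitative story under its
baseline rates; they say nothing about fit to clinical or experimental
tumor-growth data, which the model was not calibrated against here.
Parameter magnitudes span ~12 orders (carrying capacities ~10⁹ cells
against interaction rates ~10⁻¹¹), so several interaction terms are
numerically negligible except at near-capacity populations; equilibrium
formulas are evaluated in closed form to avoid that cancellation.

## Known limitations

* Uniform grids only; no adaptive stepping or non-uniform (graded)
  meshes — hence the L1 initial-layer error above.
* O(N²) memory kernels make ≳10⁵-node fractional runs slow; the
  optional history window is off by default and unvalidated against
  graded-mesh references.
* The Ulam–Hyers κ is a box-local bound; certificates do not extend to
  trajectories that leave the stated box.
* The sweep solves first-order necessary conditions; no claim of global
  optimality, and bang-bang/singular-arc structure is not analyzed.
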