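# oncofrac

A toolkit for a Caputo fractional-order model of tumor growth under
combined stem-cell therapy and chemotherapy, for researchers in
mathematical oncology and fractional dynamical systems who want to
simulate the model, classify its equilibria, certify well-posedness, and
compute optimally scheduled drug infusions.

## The model

Five compartments — tumor cells `T`, effector-immune cells `E`, normal
cells `N`, stem cells `S` and the chemotherapeutic drug amount `M` —
evolve under the left Caputo derivative of order `α ∈ (0, 1]`:

    D^α T = r1^α T (1 − b1^α T) − p3^α E T − kT^α M T
    D^α E = ρ^α − μ^α E + p1^α E S/(S+1) − p2^α (T + M) E
    D^α N = r2^α N (1 − b2^α N) + h^α S N − p4^α T N − kN^α M N
    D^α S = ± γ1^α S − kS^α M S
    D^α M = v(t) − γ2^α M

Every first-order rate enters raised to the power `α` so the dimensions
survive the change of derivative order; the infusion `v(t)` is the
control and enters unexponentiated. At `α = 1` the system is the
classical ODE model. The `±` on the stem-cell term is exposed as
`stem_sign` (+1 follows the system as written; −1 treats `γ1` as a decay
rate).

The package provides:

* **model core** — parameters (with baseline defaults), α-scaling,
  vector field, analytic Jacobian (`oncofrac.model`);
* **equilibria & stability** — closed-form tumor-free, coexisting and
  "dead" (`N = 0`) branches with existence margins, eigenvalues, the
  Matignon fractional stability test `|arg λ| > απ/2`, and the
  closed-form critical order for a complex eigenvalue pair
  (`oncofrac.equilibria`);
* **Caputo solvers** — fractional Adams–Bashforth–Moulton
  predictor–corrector, implicit L1 scheme with per-step Newton
  iteration, a right-Caputo L1 backward scheme for costates, and a
  Mittag–Leffler evaluator used as an accuracy oracle
  (`oncofrac.solvers`);
* **Ulam–Hyers certificates** — a box-restricted Lipschitz bound κ of
  the vector field, the horizon factor `Ψ = T^α/Γ(α+1)`, and the
  contraction number `Ω = Ψκ` whose `Ω < 1` verdict certifies uniqueness
  and Ulam–Hyers stability on `[0, T]` (`oncofrac.ulam_hyers`);
* **optimal chemotherapy scheduling** — minimize
  `J(v) = ∫ B1 T + ½ B2 v² dt` over `0 ≤ v(t) ≤ 1` via
  Pontryagin-type costates, the pointwise law
  `v* = clamp(−λ5/B2, 0, 1)`, and a forward–backward sweep with a
  relative-change stopping rule (`oncofrac.focp`);
* **configuration & CLI** — flat YAML scenarios, built-in study
  scenarios, delimited-text trajectory tables, and the `oncofrac`
  command with `simulate`, `equilibria`, `stability`, `uh-check`,
  `optimize` and `scenarios` subcommands.

## Worked example

Equilibria at the classical limit (`α = 1`) with the baseline rates and
steady infusion `M* = v/γ2 = 1`:

```sh
$ oncofrac equilibria --alpha 1.0
- branch: tumor_free
  point:
    T: 0.0
    E: 1.6176470586649367
    N: 1960784295.5279558
    S: 0.0
    M: 1.0
  exists: true
  existence_margins:
    normal_growth_vs_drug: 0.00215499998
  residual: 3.4363402650900657e-19
...
```

The tumor-free state carries the effector balance
`E* = ρ/(μ + p2 M*) ≈ 1.618` and normal cells just below the carrying
capacity, `N* = 1/b2 − kN M*/(r2 b2) ≈ 1.96 × 10⁹` cells; the positive
existence margin says normal-cell proliferation beats the drug-kill
threshold. Without any drug (`v = 0`) the same closed forms give
`N* ≈ 1960784313.726`, and the tumor-bearing branch restricted to
`N = 0` sits at `(T*, E*) ≈ (980392135.34, 1.476)` — the patient-death
fixed point that attracts the untreated system.

An optimized 50-day infusion schedule (order 0.95, slowly cleared drug
`γ2 = 0.1/day`, weights `B1 = B2 = 1`):

```sh
$ cat opt.yaml
control_mode: optimal
t_final: 50.0
n_steps: 1000
alpha: 0.95
$ oncofrac optimize --config opt.yaml --out run
J = 14.5151 after 10 sweeps
```

The sweep converges in 10 iterations to objective `J(v*) ≈ 14.52`,
against `J ≈ 20.30` for the constant schedule `v ≡ 0.5`: the optimal
policy doses hard early (`v ≈ 1`), then tapers to zero as the horizon
approaches, so the drug amount decays toward the end of treatment
instead of accumulating toward `v/γ2` as constant infusion does.
`run_state.csv`, `run_adjoint.csv` and `run_summary.yaml` hold the
trajectories, costates and convergence diagnostics.

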