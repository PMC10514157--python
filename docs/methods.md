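# Methods

## Model and assumptions

Two habitat patches hold subpopulations `N_A`, `N_B` that reproduce
locally and exchange individuals by *symmetric* dispersal (equal rates in
both directions).  Each patch is a **source**: isolated, it converges to
its carrying capacity.  Heterogeneity enters only through the four
demographic parameters `r_A, r_B, K_A, K_B`; the derived competition
strength `ξ_i` — `(r_i − 1)/K_i` for the Beverton–Holt map, `r_i/K_i` for
the logistic model — is exposed as a read-only accessor and never stored,
so the parameter triple can never become inconsistent.

Discrete mode applies growth *before* dispersal each generation, and the
dispersal fraction `δ` lives in `[0, 1]`: `δ = 0.5` equalizes the two
patches after a single step (perfect mixing) and `δ > 0.5` is a
replacement regime with no continuous-time analogue, up to the complete
swap at `δ = 1`.  Continuous mode couples the logistic patches with a
flux `δ_c (N_j − N_i)`, `δ_c ∈ [0, ∞)`, where perfect mixing is the limit
`δ_c → ∞`.  Discrete parameters with `r ≤ 1` are rejected rather than
treated as a limit (the competition strength degenerates there); likewise
`r ≤ 0` in continuous mode.

The quantity of interest is the dispersal response
`H(δ) = N_A(δ) + N_B(δ) − (K_A + K_B)` of the unique positive
equilibrium.  Its shape falls into four scenarios — monotonically
beneficial, unimodally beneficial, beneficial turning detrimental,
monotonically detrimental — decided entirely by closed-form inequalities
in the parameters; equal carrying capacities make dispersal exactly
neutral, and equal growth rates fold into the monotonically detrimental
shape.

## Numerical choices

* **Discrete equilibrium.**  The map is iterated from `(K_A, K_B)` (or a
  caller-supplied guess) until the sup-norm step change drops below
  `1e-12`, capped at `1e6` iterations, then polished with a 2-D `hybr`
  root solve on `x − step(x)`.  Iteration alone is globally convergent
  but slows near scenario thresholds; the polish restores ~1e-14
  residuals at negligible cost.  The polish result is accepted only if
  positive with residual below `1e-10`, otherwise the iterate stands.
* **Continuous steady state.**  Without a guess, the ODE is integrated
  with LSODA (stiff-capable: large `δ_c` makes the exchange fast) in
  chunks until the vector-field norm falls below `1e-9`, then polished
  with a Newton-type root solve using the analytic Jacobian.  Acceptance
  is judged by the residual (≤ `1e-8`) and positivity rather than the
  solver's progress flag, which can report stagnation at a fully
  converged point when `δ_c` is extreme.  Response curves pass the
  previous grid point's equilibrium as the next initial guess
  (continuation), which makes a 201-point continuous curve a fraction of
  a second.  "Infinite dispersal" is represented by the closed-form limit
  `H_c(∞)`; `δ_c = 1e4` serves as its numerical stand-in in tests.
* **Anchor point.**  `H(0)` is returned as exactly `0.0` by definition
  instead of as a numerical difference, avoiding cancellation noise.
* **Default grids.**  201 equally spaced points on `[0, 1]` (discrete);
  181 points on `[0, 10]` plus a 20-point log tail to `1e4` (continuous).
  These resolve all the worked examples' features.  The classifier
  agreement tests use a combined log + linear grid instead, because a
  response can rise and turn within `δ < 1e-3` (nearly equal growth
  rates) or only just before `δ = 1`, both invisible to a uniform grid.
* **Searches.**  The argmax of H uses a coarse grid scan (ties toward
  smaller `δ`) to bracket the maximum and bounded Brent minimization of
  `−H` to refine it — legitimate because H is provably monotone or
  unimodal; a bracket at an endpoint returns the endpoint.  The
  nontrivial zero uses the coarse-grid sign change plus `brentq`.
* **Boundary handling.**  Every threshold comparison in the classifiers
  follows the case statements verbatim; values within relative `1e-9` of
  a threshold resolve to the branch stated with "≤" and set a `boundary`
  flag so that property tests can exclude fragile draws.

## Threshold-constant orientation

The restricted-range (isolation to perfect mixing) case structure uses a
constant `κ = (r_B + √(r_A r_B) − 2)/(r_A + √(r_A r_B) − 2)` whose
printed orientation depends on which patch is labeled faster.  Under the
canonical ordering used here (`r_B ≤ r_A`) that expression is below 1 and
would empty the unimodal band `[ρ, κρ)` with `ρ = (r_B − 1)/(r_A − 1)`;
the implementation therefore uses the `> 1` orientation
`(r_fast + √(r_A r_B) − 2)/(r_slow + √(r_A r_B) − 2)` and validates it
numerically: `δ_max` crosses `0.5` exactly on the ray
`K_B/K_A = κ ρ` (checked to `1e-10`).  For the same reason the
continuous constant is exposed as
`κ_c = (r_slow + 3 r_fast)/(r_fast + 3 r_slow) > 1`, which coincides with
the printed `(r_A + 3 r_B)/(r_B + 3 r_A)` in the canonical continuous
orientation `r_A < r_B` relevant to the beneficial cases.

The restricted discrete classifier's authoritative route compares
`δ_max` and `δ̃` against `0.5` directly, sidestepping the orientation
question; the `ρ/κρ` inequality route is kept as a cross-check and the
two are asserted to agree on random non-boundary draws.

One worked continuous parameter set in circulation (`r_A = 1.1, r_B = 2,
K_A = 0.5, K_B = 1`) is sometimes labeled unimodally beneficial, but its
competition strengths satisfy `ξ_B = 2 < ξ_A = 2.2`, which places it in
the beneficial-turning-detrimental region, and its perfect-mixing limit
is negative (`H_c(∞) = −1/24`, confirmed numerically).  The classifiers
follow the inequalities; that set is excluded from the golden fixtures.

## Scenario sampling

`generate_scenario_params` draws the four parameters uniformly —
defaults `r ∈ (1.2, 4)` per generation (discrete) or `r ∈ (0.3, 3)` per
unit time (continuous), `K ∈ (0.3, 4)` in arbitrary abundance units,
ranges that keep both patches comfortably inside the source regime while
covering all four scenarios with workable acceptance rates — and keeps
draws whose analytic label matches the target and whose defining
inequalities clear a `1e-3` relative margin.  A neutral target is
sampled constructively (`K_B = K_A`).  Sampling is fully determined by
the seed; a region whose acceptance rate falls below `1e-4` raises
rather than looping forever.

What the generator emulates is parameter heterogeneity alone.  It does
not emulate demographic or environmental stochasticity, observation
error, asymmetric dispersal, or source–sink structure — so passing tests
establish correctness of the deterministic theory, not robustness of
scenario identification from noisy field data.

## Testing strategy

Closed forms are long rational expressions, so each is cross-checked two
independent ways: against computer algebra (sympy rebuilds of the same
expressions on rational inputs, catching transcription slips) and
against the numerical route (bisection zeros, bounded-search argmaxima,
finite-difference slopes at `1e-6`, map iteration at `δ = 1`, the steady
state at `δ_c = 1e4`).  The analytic classifiers are validated against
the curve-based empirical classifier on 200 seeded random draws per mode
plus patch-swap invariance; global convergence is checked with 50
parameter draws × 10 random initial states.  Problem sizes throughout
(201-point curves, 200-draw sweeps) were chosen as the smallest that
resolve every feature the theory predicts.

## Known limitations

* No closed form exists for the continuous maximizer `δ_max_c`; only its
  existence is classified (the numeric search still finds it).
* The empirical classifier is resolution-limited: responses whose
  entire positive hump is narrower than the grid spacing require a
  log-spaced grid, and features below the equilibrium solver's noise
  floor (~1e-12 discrete, ~1e-9 continuous) are undecidable numerically.
* The half-total property of the chord construction (the chord's
  identity-line crossing equals half the asymptotic total) is verified
  numerically on random draws, not proved here.
* Out of scope by design: other growth maps (Ricker, quadratic),
  asymmetric dispersal, source–sink regimes, more than two patches, and
  multi-species interactions.
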