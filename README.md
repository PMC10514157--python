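# twopatch

Tools for a classic question in spatial ecology: if two habitat patches
are connected by dispersal (a corridor, stepping stones, assisted
movement), does the **asymptotic total population size** go up or down as
dispersal increases?

The package models two *source* patches with heterogeneous demography —
intrinsic growth rates `r_A`, `r_B` and carrying capacities `K_A`, `K_B` —
coupled by symmetric dispersal, in two time modes:

* **discrete time** — Beverton–Holt recruitment
  `f_i(N) = r_i N / (1 + ξ_i N)` with competition strength
  `ξ_i = (r_i − 1)/K_i`, growth before dispersal, dispersal rate
  `δ ∈ [0, 1]` (`δ = 0.5` is perfect mixing, `δ = 1` full replacement):

  ```
  N_A,t+1 = (1 − δ) f_A(N_A,t) + δ f_B(N_B,t)
  N_B,t+1 = (1 − δ) f_B(N_B,t) + δ f_A(N_A,t)
  ```

* **continuous time** — logistic growth `f_i(N) = r_i N (1 − N/K_i)` with
  `ξ_i = r_i/K_i` and flux `δ_c (N_j − N_i)` for `δ_c ∈ [0, ∞)`.

Both systems settle onto a unique positive equilibrium
`(N_A(δ), N_B(δ))`.  The central object is the dispersal-response function

```
H(δ) = N_A(δ) + N_B(δ) − (K_A + K_B),     H(0) = 0,
```

whose sign and shape fall into exactly four scenarios: **monotonically
beneficial**, **unimodally beneficial**, **beneficial turning
detrimental**, and **monotonically detrimental** (plus the neutral case
`K_A = K_B`, where dispersal has no effect).  The package provides

* the model dynamics and numerical equilibrium/steady-state solvers
  (`models`, `equilibrium`),
* every closed-form quantity: the nontrivial zero `δ̃` of H, the maximizer
  `δ_max` and the maximum subpopulation sizes `N̄_A`, `N̄_B`, the initial
  slope `H′(0⁺)`, the full-exchange (`δ = 1`) equilibrium, the threshold
  constants `κ` (discrete) and `κ_c = (r_A + 3 r_B)/(r_B + 3 r_A)`
  (continuous), and the perfect-mixing limits `H_c(∞)`, `H_c′(0⁺)`
  (`closed_forms`),
* exact parameter-condition classifiers for both modes and both dispersal
  ranges, with an empirical (curve-based) classifier as oracle
  (`classify`),
* the chord construction at the discrete equilibrium, the
  overcrowding/undercrowding decomposition of H, and the
  competition-strength marker `N◆ = K/(√r + 1)` (`geometry`),
* seeded sampling of parameter sets inside a scenario region
  (`sampling`), plotting, and a thin `twopatch` CLI.

## Worked example

```python
from twopatch import PatchParams, classify, summarize, numeric_zero_H

params = PatchParams(r_A=3.4, r_B=1.5, K_A=8.4, K_B=1.37)
print(classify(params).label.value)       # beneficial_turning_detrimental
s = summarize(params)
print(round(s.delta_tilde, 6))            # 0.374844
print(round(numeric_zero_H(params), 6))   # 0.374844
print(round(s.max_total, 4), round(s.argmax_delta, 4))  # 10.1328 0.1284
```

A little dispersal pushes the total above the isolated sum
`K_A + K_B = 9.77`, peaking at `10.13` at `δ ≈ 0.128`; beyond
`δ̃ ≈ 0.3748` the connection is a net loss.  The closed-form zero and the
bisection zero of the numeric curve agree to six decimals.

The `examples/` directory holds one narrative script per capability
(response curves, closed forms, the continuous model, the chord
construction, scenario sampling); each prints the numbers it computes and
a line on what they mean.  The same functionality is scriptable from the
shell:

```
twopatch classify --mode continuous --rA 0.5 --rB 2 --KA 0.5 --KB 1
twopatch curve --mode discrete --rA 3 --rB 1.5 --KA 2 --KB 1.5 --out curve.csv
```

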