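"""Closed-form thresholds versus their numerical counterparts.

For the beneficial-turning-detrimental system, the dispersal rate at
which the benefit is lost (the nontrivial zero of H) and the rate
maximizing the total population both have exact expressions; here they
are compared against bisection and bounded search on the numeric curve.
"""

from twopatch import (
    PatchParams,
    delta_max,
    delta_tilde,
    max_population_summary,
    numeric_argmax_H,
    numeric_zero_H,
    summarize,
)

params = PatchParams(r_A=3.4, r_B=1.5, K_A=8.4, K_B=1.37)

dt = delta_tilde(params)
print(f"closed-form zero of H : {dt:.6f}")
print(f"numeric bisection zero: {numeric_zero_H(params):.6f}")

dm = delta_max(params)
d_num, h_num = numeric_argmax_H(params, (0.0, 1.0))
print(f"closed-form argmax    : {dm:.6f}")
print(f"numeric search argmax : {d_num:.6f}  (H there = {h_num:+.4f})")

mx, amx, NA1, NB1 = max_population_summary(params)
print(f"max asymptotic total  : {mx:.4f} at delta = {amx:.4f} "
      f"(isolated total {params.K_A + params.K_B:.2f})")

print()
print("Summary object (JSON-ready):")
for key, value in summarize(params).to_dict().items():
    print(f"  {key}: {value}")
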