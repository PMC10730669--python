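"""Nullclines, interior equilibrium and local stability in the (N1, N2) plane.

Contrasts a weak-competition setting (stable interior node) with its
strong-competition counterpart (saddle + bistability), checking the
nullcline intersection against the Jacobian spectrum.
"""

import numpy as np

from delaylv import (
    classify,
    equilibrium_state,
    initial_state,
    nullclines,
    stability_from_jacobian,
    steady_state,
    load_scenario,
)

for name, story in [("fig4a", "weak competition (b = 0.5)"),
                    ("fig5a", "strong competition (b = 2)")]:
    mdl = load_scenario(name).model
    rep = classify(mdl)
    l1, l2 = nullclines(mdl)
    print(f"{name}: {story}")
    print(f"  nullcline 1: {l1.coef_self:.3f} N1 + {l1.coef_other:.3f} N2 = {l1.constant:.3f}")
    print(f"  nullcline 2: {l2.coef_self:.3f} N2 + {l2.coef_other:.3f} N1 = {l2.constant:.3f}")
    print(f"  intersection: ({rep.coexistence[0]:.4f}, {rep.coexistence[1]:.4f})")
    res = stability_from_jacobian(mdl, equilibrium_state(mdl, *rep.coexistence))
    print(f"  rightmost eigenvalue Re = {res.max_real:+.4f}  -> "
          f"{'attracting node' if res.stable else 'saddle'}")
    if rep.label == "bistable":
        for ic in [(0.9, 0.1), (0.1, 0.9)]:
            out = steady_state(mdl, initial_state(mdl, *ic), max_time=2000.0)
            print(f"  start N={ic} -> {out.label}, N = {np.round(out.final_N, 4)}")
    print()
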