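"""Larval competition between two malaria vectors.

Anopheles gambiae s.s. (species 1) and An. arabiensis (species 2) mature in
shared water reservoirs; competition acts on larvae, adults feed freely.
Mean maturation 13 vs 14 days, immature mortality 0.2 vs 0.3 per day,
5 eggs per adult per day, adult mortality 0.1 per day.  We compare a
heterogeneous maturation delay (shape 1) with a nearly deterministic one
(shape 20) under weak and strong interspecific pressure.
"""

from delaylv import classify, load_scenario, steady_state

for name, story in [
    ("fig8a", "weak pressure, heterogeneous delays (shape 1)"),
    ("fig8a_p20", "weak pressure, near-deterministic delays (shape 20)"),
    ("fig8c", "strong pressure, heterogeneous delays (shape 1)"),
    ("fig8d", "strong pressure, arabiensis-favouring start (0.05, 0.6)"),
]:
    sc = load_scenario(name)
    rep = classify(sc.model)
    out = steady_state(sc.model, sc.initial_state(), max_time=2500.0)
    print(f"{name}: {story}")
    print(f"  classification: {rep.label}")
    print(f"  after {out.time:.0f} d: gambiae N1 = {out.final_N[0]:.4f}, "
          f"arabiensis N2 = {out.final_N[1]:.4f}  ({out.label})")
    print()

print("Delay heterogeneity is protective: with shape 1 the species can")
print("coexist (or the disadvantaged one can still win from a favourable")
print("start), while the same demography with near-discrete delays tips to")
print("exclusion — a model that wrongly assumes a fixed delay misses this.")
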