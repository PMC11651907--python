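"""Superspreaders versus superspreading events in synthetic networks.

In each time step the "top group" is the smallest set of individuals
carrying 80% of the contacts.  Individuals in that group for at least
half of the steps behave like superspreaders (persistently central,
predictable); individuals in it for under a quarter of the steps would
drive superspreading events (occasionally central, unpredictable).

Compares a homogeneous dynamic network (p80 = 0.8) with an overdispersed
one calibrated so only half the population carries 80% of contacts
(p80 = 0.5), against the geometric reference curve p80**s.
"""

import numpy as np

from tempnet import (
    DegreeLaw,
    GeneratorConfig,
    calibrate_dispersion,
    classify,
    dynamic_reference_curve,
    generate_fully_dynamic,
    persistence_curve,
    trajectory,
)

N, T = 400, 10

disp = calibrate_dispersion(5, 0.5, N, seed=0)
print(f"negative-binomial dispersion {disp:.3f} gives p80 = 0.5 at mean degree 5\n")

for label, law in [
    ("homogeneous (constant degree, p80 = 0.8)", DegreeLaw.constant(5)),
    (f"overdispersed (p80 = 0.5)", DegreeLaw.negative_binomial(5, disp)),
]:
    cfg = GeneratorConfig(n=N, t=T, degree_law=law, seed=11, shuffle_degrees=True)
    series = generate_fully_dynamic(cfg)
    traj = trajectory(series, rng=np.random.default_rng(1))  # random tie-breaks
    groups = classify(traj)
    curve = persistence_curve(traj)
    p80 = float(np.mean(traj.p80_per_step))
    print(f"{label}: fully dynamic, {T} steps")
    print(f"  mean per-step top-group fraction : {p80:.2f}")
    print(f"  superspreaders (>= S/2 steps)    : {len(groups['superspreaders'])/N:.1%}")
    print(f"  superspreading-event drivers     : {len(groups['sse_drivers'])/N:.1%}")
    print(f"  neither                          : {len(groups['neither'])/N:.1%}")
    ref = dynamic_reference_curve(p80, T)
    frac_all = 1 - curve.rho[-2]  # identified in all S steps
    print(f"  identified in all {T} steps       : {frac_all:.1%} "
          f"(geometric reference p80^S = {ref[-1]:.1%})\n")

print("Overdispersion shrinks the persistently identifiable group: targeting")
print("'superspreaders' found in a short survey misses most future spreading.")
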