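"""Simulate one microbe on one substrate and watch the basis change.

The capped-growth community grows at its maximum rate (the growth cap binds)
until glucose falls to the point where the uptake bound becomes the active
constraint; the simulator detects that event, switches basis, and continues
with substrate-limited dynamics.  The event time is known in closed form:
t* = ln(51)/10.
"""

import numpy as np

import dfbanet as dn
from dfbanet import fixtures as fx

model, env, x0 = fx.capped_growth()  # kappa=1, cap=10, x0=0.1, y0=30
result = dn.simulate_community([model], env, x0, t_final=5.0)

print(f"status: {result.status}, segments: {len(result.segments)}")
for tr in result.transitions:
    print(f"transition at t = {tr.time:.6f}: {tr.violated_constraint} "
          f"({tr.action}, microbe {','.join(tr.microbe_ids)})")
print(f"analytic event time ln(51)/10 = {np.log(51.0) / 10.0:.6f}")
print(f"final biomass x(5) = {result.x[-1, 0]:.4f} gDW "
      f"(asymptote x0 + y0/2 = {x0[0] + env.initial_amounts[0] / 2:.1f})")
print(f"remaining glucose y(5) = {result.y[-1, 0]:.2e} mmol")

# The first segment's growth is intrinsic (the cap, not glucose, limits it);
# the second is substrate-limited, with growth proportional to glucose.
for k, seg in enumerate(result.segments):
    c = seg.coeffs
    print(f"segment {k} [{seg.t_start:.3f}, {seg.t_end:.3f}): "
          f"intrinsic growth C = {c.intrinsic_growth[0]:g}, "
          f"metabolite-dependent terms a = {dict(c.growth_coeffs[0])}")
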