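"""Read interaction networks off a diauxic-shift simulation.

A single microbe shares a fixed transport capacity between glucose (high
yield) and a secondary substrate.  While glucose saturates the capacity the
growth rate is intrinsic; once glucose becomes rate-limiting, spare capacity
flows to substrate 2 and new network edges appear — including a positive
microbe-mediated glucose -> substrate2 edge (more glucose spares substrate 2).
"""

import dfbanet as dn
from dfbanet import fixtures as fx

model, env, x0 = fx.diauxie()
result = dn.simulate_community([model], env, x0, t_final=3.0)
print(f"{len(result.segments)} segments; transitions:")
for tr in result.transitions:
    print(f"  t = {tr.time:.4f}: {tr.violated_constraint}")

for k, seg in enumerate(result.segments):
    print(f"\nsegment {k} [{seg.t_start:.3f}, {seg.t_end:.3f})")
    sm = dn.species_metabolite_network(seg, k)
    for e in sm.edges:
        med = f" (mediated by {e.mediator})" if e.mediator else ""
        print(f"  {e.source} -> {e.target}: {e.weight:+.3f} [{e.term_kind}]{med}")
    mm = dn.metabolite_metabolite_network(seg, k)
    for e in mm.edges:
        print(f"  {e.source} -> {e.target}: {e.weight:+.3f} "
              f"[via microbe {e.microbe}]")

# Duration-weighted summary across segments: the mean network is the
# time-averaged interaction structure, the variance network highlights the
# edges whose strength changed between segments.
series = dn.series_from_result(result, "species_metabolite")
mean, var = dn.summarize_series(series)
print("\ntime-averaged species-metabolite network:")
for e in mean.edges:
    v = next(x.weight for x in var.edges if x.key() == e.key())
    print(f"  {e.source} -> {e.target} [{e.term_kind}]: "
          f"mean {e.weight:+.3f}, variance {v:.3f}")
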