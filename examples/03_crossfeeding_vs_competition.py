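"""Species-species heuristic: cross-feeding vs resource competition.

The species-species weight w~_ij sums, over all metabolites l, the product
of the effect of microbe i on l and the effect of l on the growth of microbe
j (paths of length two).  Consumption of a growth-limiting resource gives
negative products (competition); secretion of another microbe's substrate
gives positive products (cross-feeding).
"""

import dfbanet as dn
from dfbanet import fixtures as fx

for label, (models, env, x0) in [("cross-feeding pair", fx.crossfeed_pair()),
                                 ("competition pair", fx.competition_pair())]:
    result = dn.simulate_community(models, env, x0, t_final=5.0)
    mean, _ = dn.summarize_series(dn.series_from_result(result, "species_species"))
    print(f"{label}: time-averaged species-species edges")
    for e in mean.edges:
        kind = "cross-feeding" if e.weight > 0 else "competition"
        print(f"  {e.source} -> {e.target}: {e.weight:+.4f} "
              f"via {', '.join(e.metabolites)}  ({kind})")

    sm_mean, _ = dn.summarize_series(
        dn.series_from_result(result, "species_metabolite"))
    ids = [m.id for m in models]
    ranked = dn.candidate_mediators(sm_mean, ids[0], ids[1], required_sign=+1)
    if ranked:
        print(f"  strongest positive mediator {ids[0]} -> {ids[1]}: "
              f"{ranked[0][0]} (path product {ranked[0][1]:+.4f})")
    print()
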