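"""Edge mapping, path heuristic, summaries, baseline contrast, mediators."""

import numpy as np
import pytest

import dfbanet as dn
from dfbanet import fixtures as fx
from dfbanet.networks import InteractionEdge, InteractionNetwork


def _edge(net, source, target, term_kind=None):
    out = [e for e in net.edges if e.source == source and e.target == target
           and (term_kind is None or e.term_kind == term_kind)]
    assert len(out) == 1, (source, target, term_kind, out)
    return out[0]


# -- species-metabolite mapping ---------------------------------------------

def test_monod_segment_edge_mapping(simulated):
    net = dn.species_metabolite_network(simulated["monod_linear"].segments[0])
    assert len(net.edges) == 2
    growth = _edge(net, "glucose", "M", "growth")
    assert growth.weight == pytest.approx(0.5)
    consumption = _edge(net, "M", "glucose", "self_mediated")
    assert consumption.weight == pytest.approx(-1.0)  # effect-signed
    assert consumption.raw_coeff == pytest.approx(1.0)  # raw as in the ODE


def test_capped_segment1_intrinsic_growth_pattern(simulated):
    net = dn.species_metabolite_network(simulated["capped_growth"].segments[0])
    assert not [e for e in net.edges if e.term_kind == "growth"]
    exchange = _edge(net, "M", "glucose", "constant_exchange")
    assert exchange.weight == pytest.approx(-20.0)


def test_cross_mediated_edge_carries_mediator(simulated):
    net = dn.species_metabolite_network(simulated["diauxie"].segments[1])
    cross = _edge(net, "D", "substrate2", "cross_mediated")
    assert cross.mediator == "glucose"
    assert cross.weight == pytest.approx(1.0)  # spare capacity: production-signed


def test_all_zero_coefficients_empty_network(simulated):
    seg = simulated["monod_linear"].segments[0]
    import copy
    empty = copy.copy(seg)
    empty.coeffs = copy.deepcopy(seg.coeffs)
    empty.coeffs.intrinsic_growth[:] = 0.0
    empty.coeffs.growth_coeffs[0].clear()
    empty.coeffs.constant_exchange[:] = 0.0
    empty.coeffs.mediated_exchange[0].clear()
    assert dn.species_metabolite_network(empty).edges == []


def test_network_builders_are_pure(simulated):
    seg = simulated["diauxie"].segments[1]
    n1 = dn.species_metabolite_network(seg)
    n2 = dn.species_metabolite_network(seg)
    assert n1.edges == n2.edges


# -- metabolite-metabolite ---------------------------------------------------

def test_monod_metabolite_self_loop(simulated):
    net = dn.metabolite_metabolite_network(simulated["monod_linear"].segments[0])
    assert len(net.edges) == 1
    loop = net.edges[0]
    assert (loop.source, loop.target) == ("glucose", "glucose")
    assert loop.weight == pytest.approx(-1.0)
    assert loop.microbe == "M"


def test_self_loops_excludable(simulated):
    net = dn.metabolite_metabolite_network(
        simulated["monod_linear"].segments[0], include_self_loops=False)
    assert net.edges == []


def test_diauxie_glucose_spares_substrate2(simulated):
    net = dn.metabolite_metabolite_network(simulated["diauxie"].segments[1])
    cross = _edge(net, "glucose", "substrate2")
    assert cross.weight > 0  # more glucose -> more spare capacity -> less uptake
    assert cross.microbe == "D"


# -- species-species heuristic ----------------------------------------------

def _sm_net(edges, microbes, mets):
    nodes = {m: "microbe" for m in microbes}
    nodes.update({m: "metabolite" for m in mets})
    return InteractionNetwork(kind="species_metabolite", nodes=nodes,
                              edges=list(edges))


def test_single_path_product():
    net = _sm_net([
        InteractionEdge("A", "s", -1.0, 1.0, "self_mediated", microbe="A"),
        InteractionEdge("s", "B", 0.5, 0.5, "growth", microbe="B"),
    ], ["A", "B"], ["s"])
    ss = dn.species_species_network(net)
    e = _edge(ss, "A", "B")
    assert e.weight == pytest.approx(-0.5)
    assert e.metabolites == ("s",)


def test_cancelling_paths_drop_edge():
    net = _sm_net([
        InteractionEdge("A", "s", -1.0, 1.0, "constant_exchange", microbe="A"),
        InteractionEdge("s", "B", 0.5, 0.5, "growth", microbe="B"),
        InteractionEdge("A", "t", 2.0, -2.0, "constant_exchange", microbe="A"),
        InteractionEdge("t", "B", 0.25, 0.25, "growth", microbe="B"),
    ], ["A", "B"], ["s", "t"])
    ss = dn.species_species_network(net)
    assert not [e for e in ss.edges if e.source == "A" and e.target == "B"]


@pytest.mark.parametrize("seed", range(100))
def test_heuristic_equals_exhaustive_path_enumeration(seed):
    """Random networks: sum over length-2 paths, computed two ways, agree."""
    rng = np.random.default_rng(seed)
    microbes = [f"X{i}" for i in range(rng.integers(2, 4))]
    mets = [f"Y{j}" for j in range(rng.integers(1, 5))]
    edges = []
    for mi in microbes:
        for met in mets:
            if rng.random() < 0.6:
                w = float(rng.normal())
                edges.append(InteractionEdge(mi, met, w, -w, "constant_exchange",
                                             microbe=mi))
            if rng.random() < 0.3:
                w = float(rng.normal())
                edges.append(InteractionEdge(mi, met, w, -w, "cross_mediated",
                                             mediator=mets[0], microbe=mi))
            if rng.random() < 0.5:
                w = float(rng.normal())
                edges.append(InteractionEdge(met, mi, w, w, "growth", microbe=mi))
    net = _sm_net(edges, microbes, mets)
    ss = dn.species_species_network(net, weight_eps=0.0)
    got = {(e.source, e.target): e.weight for e in ss.edges}
    # brute force: enumerate every pair of edges forming X_i -> Y -> X_j
    brute = {}
    for e1 in edges:
        if e1.term_kind == "growth":
            continue
        for e2 in edges:
            if e2.term_kind != "growth" or e2.source != e1.target:
                continue
            key = (e1.source, e2.target)
            brute[key] = brute.get(key, 0.0) + e1.weight * e2.weight
    brute = {k: v for k, v in brute.items() if v != 0.0}
    assert set(got) == set(brute)
    for k in brute:
        assert got[k] == pytest.approx(brute[k], abs=1e-12)


def test_crossfeeding_and_competition_signs(simulated):
    ss_cf, _ = dn.summarize_series(
        dn.series_from_result(simulated["crossfeed_pair"], "species_species"))
    assert _edge(ss_cf, "A", "B").weight > 0  # cross-feeding
    ss_cp, _ = dn.summarize_series(
        dn.series_from_result(simulated["competition_pair"], "species_species"))
    pq, qp = _edge(ss_cp, "P", "Q").weight, _edge(ss_cp, "Q", "P").weight
    assert pq < 0 and qp < 0
    assert pq == pytest.approx(qp, abs=1e-9)  # identical models -> symmetric


def test_consumers_have_negative_outgoing_weight(simulated):
    """Effect-sign convention: net consumption -> negative X->Y aggregate."""
    for name, res in simulated.items():
        sm, _ = dn.summarize_series(dn.series_from_result(res, "species_metabolite"))
        for i, mid in enumerate(res.microbe_ids):
            for j, met in enumerate(res.metabolite_ids):
                consumed = res.y[0, j] - res.y[-1, j]
                if consumed <= 1e-6:
                    continue
                w = sum(e.weight for e in sm.edges
                        if e.source == mid and e.target == met)
                if w != 0.0:
                    assert w < 0, (name, mid, met, w)


def test_species_species_needs_right_input(simulated):
    mm = dn.metabolite_metabolite_network(simulated["monod_linear"].segments[0])
    with pytest.raises(ValueError):
        dn.species_species_network(mm)


# -- summaries ---------------------------------------------------------------

def _net_with_weight(w, t0, t1):
    return InteractionNetwork(
        kind="species_metabolite",
        nodes={"A": "microbe", "s": "metabolite"},
        edges=[InteractionEdge("A", "s", w, -w, "constant_exchange", microbe="A")],
        t_start=t0, t_end=t1)


def test_single_segment_zero_variance():
    mean, var = dn.summarize_series(dn.NetworkSeries([_net_with_weight(2.5, 0, 1)]))
    assert mean.edges[0].weight == pytest.approx(2.5)
    assert var.edges[0].weight == pytest.approx(0.0)


def test_equal_duration_mean_and_variance():
    series = dn.NetworkSeries([_net_with_weight(1.0, 0, 1),
                               _net_with_weight(3.0, 1, 2)])
    mean, var = dn.summarize_series(series)
    assert mean.edges[0].weight == pytest.approx(2.0)
    assert var.edges[0].weight == pytest.approx(1.0)


def test_duration_weighted_mean_and_variance_with_absent_edge():
    series = dn.NetworkSeries([
        _net_with_weight(4.0, 0, 1),
        InteractionNetwork(kind="species_metabolite",
                           nodes={"A": "microbe", "s": "metabolite"},
                           edges=[], t_start=1, t_end=4),  # absent edge = 0
    ])
    mean, var = dn.summarize_series(series)
    assert mean.edges[0].weight == pytest.approx(1.0)  # (1*4 + 3*0)/4
    assert var.edges[0].weight == pytest.approx(3.0)   # (1*9 + 3*1)/4


def test_all_equal_networks_zero_variance_everywhere(simulated):
    series = dn.NetworkSeries([_net_with_weight(1.5, 0, 1),
                               _net_with_weight(1.5, 1, 3)])
    _, var = dn.summarize_series(series)
    assert all(e.weight == pytest.approx(0.0) for e in var.edges)


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        dn.summarize_series(dn.NetworkSeries([]))


# -- differences and shifts --------------------------------------------------

def test_identical_networks_zero_difference():
    n = _net_with_weight(-2.0, 0, 1)
    diff, only = dn.network_difference(n, n)
    assert only == []
    assert diff.edges[0].weight == pytest.approx(0.0)


def test_signed_strength_difference():
    na = _net_with_weight(-2.0, 0, 1)
    nb = _net_with_weight(-0.5, 0, 1)
    diff, _ = dn.network_difference(na, nb)
    assert diff.edges[0].weight == pytest.approx(1.5)  # |−2| − |−0.5|


def test_disjoint_edges_reported_not_differenced():
    na = _net_with_weight(1.0, 0, 1)
    nb = InteractionNetwork(
        kind="species_metabolite", nodes={"B": "microbe", "t": "metabolite"},
        edges=[InteractionEdge("B", "t", 1.0, -1.0, "constant_exchange",
                               microbe="B")], t_start=0, t_end=1)
    diff, only = dn.network_difference(na, nb)
    assert diff.edges == []
    assert len(only) == 2


def test_network_type_mismatch_rejected(simulated):
    sm = dn.species_metabolite_network(simulated["monod_linear"].segments[0])
    mm = dn.metabolite_metabolite_network(simulated["monod_linear"].segments[0])
    with pytest.raises(ValueError):
        dn.network_difference(sm, mm)


def test_connection_shift_values():
    def net(w1, w2):
        return InteractionNetwork(
            kind="species_metabolite",
            nodes={"A": "microbe", "s": "metabolite", "t": "metabolite"},
            edges=[
                InteractionEdge("A", "s", w1, -w1, "constant_exchange", microbe="A"),
                InteractionEdge("A", "t", w2, -w2, "constant_exchange", microbe="A"),
            ])
    na, nb = net(1.0, -2.0), net(0.5, -1.0)
    assert dn.connection_shift("A", na, nb) == pytest.approx(0.75)
    assert dn.connection_shift("A", na, na) == pytest.approx(0.0)


def test_connection_shift_errors():
    na = _net_with_weight(1.0, 0, 1)
    nb = InteractionNetwork(kind="species_metabolite",
                            nodes={"A": "microbe"}, edges=[])
    with pytest.raises(ValueError, match="no connections shared"):
        dn.connection_shift("A", na, nb)
    with pytest.raises(ValueError, match="absent"):
        dn.connection_shift("Z", na, nb)


# -- FBA-direct baseline -----------------------------------------------------

def test_fba_direct_monod_edges(monod):
    models, env, _ = monod
    net = dn.fba_direct_network(models, env, np.array([2.0]))
    flux = _edge(net, "M", "glucose", "flux")
    assert flux.weight == pytest.approx(-2.0)
    marker = _edge(net, "glucose", "M", "consumed_marker")
    assert marker.weight == 1.0


def test_untouched_metabolite_isolated(monod):
    models, env, _ = monod
    env2 = dn.EnvironmentSpec(metabolite_ids=["glucose", "inert"],
                              initial_amounts=np.array([2.0, 5.0]))
    net = dn.fba_direct_network(models, env2, env2.initial_amounts)
    assert "inert" in net.nodes
    assert not [e for e in net.edges if "inert" in (e.source, e.target)]


def test_baseline_has_at_least_as_many_growth_direction_edges(simulated,
                                                              all_fixture_communities):
    """The FBA-direct baseline marks every consumed metabolite as
    growth-affecting; the segment network keeps only rate-limiting ones."""
    for name, res in simulated.items():
        models, env, x0 = all_fixture_communities[name]
        for k, seg in enumerate(res.segments):
            idx = np.searchsorted(res.times, seg.t_start + 1e-9)
            y = np.maximum(res.y[min(idx, len(res.times) - 1)], 0.0)
            direct = dn.fba_direct_network(models, env, y)
            n_markers = sum(e.term_kind == "consumed_marker" for e in direct.edges)
            sm = dn.species_metabolite_network(seg, k)
            n_growth = sum(e.term_kind == "growth" for e in sm.edges)
            assert n_markers >= n_growth, (name, k)
    # strict excess on the first diauxie segment (growth there is intrinsic)
    res = simulated["diauxie"]
    models, env, x0 = all_fixture_communities["diauxie"]
    direct = dn.fba_direct_network(models, env, env.initial_amounts)
    n_markers = sum(e.term_kind == "consumed_marker" for e in direct.edges)
    n_growth = sum(e.term_kind == "growth"
                   for e in dn.species_metabolite_network(res.segments[0]).edges)
    assert n_markers > n_growth


# -- mediators and significance ----------------------------------------------

def test_crossfeed_candidate_mediator(simulated):
    mean, _ = dn.summarize_series(
        dn.series_from_result(simulated["crossfeed_pair"], "species_metabolite"))
    ranked = dn.candidate_mediators(mean, "A", "B", required_sign=+1)
    assert [m for m, _ in ranked] == ["acetate"]
    assert dn.candidate_mediators(mean, "B", "A", required_sign=+1) == []


def test_candidate_mediators_ranked_by_strength():
    net = _sm_net([
        InteractionEdge("A", "s", -0.6, 0.6, "constant_exchange", microbe="A"),
        InteractionEdge("s", "B", -0.5, -0.5, "growth", microbe="B"),
        InteractionEdge("A", "t", -1.0, 1.0, "constant_exchange", microbe="A"),
        InteractionEdge("t", "B", -0.8, -0.8, "growth", microbe="B"),
    ], ["A", "B"], ["s", "t"])
    ranked = dn.candidate_mediators(net, "A", "B", required_sign=+1)
    assert [m for m, _ in ranked] == ["t", "s"]  # 0.8 before 0.3


def test_candidate_mediators_unknown_microbe(simulated):
    mean, _ = dn.summarize_series(
        dn.series_from_result(simulated["crossfeed_pair"], "species_metabolite"))
    with pytest.raises(ValueError):
        dn.candidate_mediators(mean, "nope", "B", +1)


def test_significant_metabolites_partition(simulated):
    sig = dn.significant_metabolites(simulated["crossfeed_pair"])
    assert "glucose" in sig["consumed"]
    # acetate is produced then eaten; whichever way, constant metabolites
    # must never appear
    res = simulated["crossfeed_pair"]
    j = res.metabolite_ids.index("acetate")
    rel = abs(res.y[-1, j] - res.y[0, j]) / max(res.y[0, j], 1e-9)
    in_report = "acetate" in sig["consumed"] + sig["produced"]
    assert in_report == (rel > 0.01)


def test_significant_metabolites_threshold_and_floor():
    res = dn.DfbaResult(
        microbe_ids=[], metabolite_ids=["a", "b", "c"],
        segments=[], times=np.array([0.0, 1.0]),
        x=np.zeros((2, 0)),
        y=np.array([[10.0, 10.0, 0.0], [9.85, 10.0, 0.5]]),
        transitions=[], status="reached_t_final")
    sig = dn.significant_metabolites(res, threshold=0.01)
    assert sig == {"consumed": ["a"], "produced": ["c"]}
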