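"""Interaction networks read off the segment ODE coefficients.

Three network types are built per segment:

* species-metabolite: growth edges Y_j -> X_i (weight a_ij) and exchange
  edges X_i -> Y_l from the constant (D_il), self-mediated (b_ill) and
  cross-mediated (b_ijl, j != l) terms of the metabolite equation;
* metabolite-metabolite: Y_j -> Y_l for each mediated term, labelled by the
  microbe whose metabolism contributes it;
* species-species: the length-2-path heuristic
  w~_ij = sum_l w_il * w_lj over metabolites l.

Edge weights are EFFECT-signed: an exchange edge carries -raw_coeff, so a
consumption term (positive raw b) becomes a negative edge, which is what
makes competition products in the species-species heuristic come out
negative.  The raw coefficient is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import DfbaResult, ODESegment

__all__ = [
    "InteractionEdge",
    "InteractionNetwork",
    "NetworkSeries",
    "species_metabolite_network",
    "metabolite_metabolite_network",
    "species_species_network",
    "series_from_result",
    "summarize_series",
    "network_difference",
    "connection_shift",
    "fba_direct_network",
    "candidate_mediators",
    "significant_metabolites",
]

WEIGHT_EPS = 1e-10


@dataclass(frozen=True)
class InteractionEdge:
    """A signed, mediator-annotated interaction."""

    source: str
    target: str
    weight: float
    raw_coeff: float
    term_kind: str  # growth | constant_exchange | self_mediated | cross_mediated | heuristic | flux | consumed_marker
    mediator: Optional[str] = None
    microbe: Optional[str] = None
    segment_index: int = -1
    metabolites: Tuple[str, ...] = ()  # species-species: contributing metabolites

    def key(self) -> Tuple:
        """Identity for averaging/differencing across segments."""
        return (self.source, self.target, self.term_kind, self.mediator, self.microbe)


@dataclass
class InteractionNetwork:
    """Directed multigraph of microbe/metabolite nodes with signed edges."""

    kind: str  # "species_metabolite" | "metabolite_metabolite" | "species_species" | "fba_direct"
    nodes: Dict[str, str]  # node id -> "microbe" | "metabolite"
    edges: List[InteractionEdge]
    t_start: float = 0.0
    t_end: float = 0.0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def edges_from(self, node: str) -> List[InteractionEdge]:
        return [e for e in self.edges if e.source == node]

    def edges_to(self, node: str) -> List[InteractionEdge]:
        return [e for e in self.edges if e.target == node]


@dataclass
class NetworkSeries:
    """Ordered per-segment networks with durations."""

    networks: List[InteractionNetwork]

    @property
    def total_time(self) -> float:
        return sum(n.duration for n in self.networks)


def _nodes_for(segment: ODESegment) -> Dict[str, str]:
    nodes = {mid: "microbe" for mid in segment.coeffs.microbe_ids}
    nodes.update({met: "metabolite" for met in segment.coeffs.metabolite_ids})
    return nodes


def species_metabolite_network(segment: ODESegment, segment_index: int = -1,
                               weight_eps: float = WEIGHT_EPS) -> InteractionNetwork:
    """Per-segment microbe/metabolite network from the ODE coefficients.

    Growth edges Y_j -> X_i keep the raw sign (weight a_ij); all edges into
    a metabolite are effect-signed (weight -raw), so consumption is negative
    and production positive.  Near-zero weights are dropped.
    """
    c = segment.coeffs
    mets = c.metabolite_ids
    edges: List[InteractionEdge] = []
    for i, mid in enumerate(c.microbe_ids):
        for j, a in sorted(c.growth_coeffs[i].items()):
            if abs(a) < weight_eps:
                continue
            edges.append(InteractionEdge(
                source=mets[j], target=mid, weight=a, raw_coeff=a,
                term_kind="growth", microbe=mid, segment_index=segment_index))
        for l in range(len(mets)):
            d = c.constant_exchange[i, l]
            if abs(d) >= weight_eps:
                edges.append(InteractionEdge(
                    source=mid, target=mets[l], weight=-d, raw_coeff=d,
                    term_kind="constant_exchange", microbe=mid,
                    segment_index=segment_index))
        for (j, l), b in sorted(c.mediated_exchange[i].items()):
            if abs(b) < weight_eps:
                continue
            kind = "self_mediated" if j == l else "cross_mediated"
            edges.append(InteractionEdge(
                source=mid, target=mets[l], weight=-b, raw_coeff=b,
                term_kind=kind,
                mediator=mets[j] if j != l else None,
                microbe=mid, segment_index=segment_index))
    return InteractionNetwork(
        kind="species_metabolite", nodes=_nodes_for(segment), edges=edges,
        t_start=segment.t_start, t_end=segment.t_end)


def metabolite_metabolite_network(segment: ODESegment, segment_index: int = -1,
                                  include_self_loops: bool = True,
                                  weight_eps: float = WEIGHT_EPS) -> InteractionNetwork:
    """Microbe-mediated metabolite network: Y_j -> Y_l per mediated term.

    Parallel edges contributed by different microbes are kept separate and
    labelled with the contributing microbe.
    """
    c = segment.coeffs
    mets = c.metabolite_ids
    edges: List[InteractionEdge] = []
    for i, mid in enumerate(c.microbe_ids):
        for (j, l), b in sorted(c.mediated_exchange[i].items()):
            if abs(b) < weight_eps:
                continue
            if j == l and not include_self_loops:
                continue
            edges.append(InteractionEdge(
                source=mets[j], target=mets[l], weight=-b, raw_coeff=b,
                term_kind="self_mediated" if j == l else "cross_mediated",
                microbe=mid, segment_index=segment_index))
    nodes = {met: "metabolite" for met in mets}
    return InteractionNetwork(
        kind="metabolite_metabolite", nodes=nodes, edges=edges,
        t_start=segment.t_start, t_end=segment.t_end)


def species_species_network(net: InteractionNetwork,
                            include_mediated: bool = True,
                            weight_eps: float = WEIGHT_EPS) -> InteractionNetwork:
    """Length-2-path heuristic over a species-metabolite network.

    w~_ij = sum_l w_il * w_lj, where w_il aggregates every X_i -> Y_l edge
    (constant, self- and cross-mediated; mediated terms excludable) and
    w_lj aggregates Y_l -> X_j growth edges.  The contributing metabolites
    and their per-metabolite path products are recorded on each edge.
    """
    if net.kind != "species_metabolite":
        raise ValueError("species_species_network needs a species-metabolite network")
    microbes = sorted(n for n, t in net.nodes.items() if t == "microbe")
    mets = sorted(n for n, t in net.nodes.items() if t == "metabolite")
    w_out: Dict[Tuple[str, str], float] = {}
    w_in: Dict[Tuple[str, str], float] = {}
    for e in net.edges:
        if e.term_kind == "growth":
            w_in[(e.source, e.target)] = w_in.get((e.source, e.target), 0.0) + e.weight
        else:
            if not include_mediated and e.term_kind in ("self_mediated", "cross_mediated"):
                continue
            w_out[(e.source, e.target)] = w_out.get((e.source, e.target), 0.0) + e.weight
    edges: List[InteractionEdge] = []
    for mi in microbes:
        for mj in microbes:
            total = 0.0
            contributing: List[str] = []
            for met in mets:
                wil = w_out.get((mi, met), 0.0)
                wlj = w_in.get((met, mj), 0.0)
                prod = wil * wlj
                if prod != 0.0:
                    total += prod
                    contributing.append(met)
            if not contributing or abs(total) <= weight_eps:
                continue
            edges.append(InteractionEdge(
                source=mi, target=mj, weight=total, raw_coeff=total,
                term_kind="heuristic", metabolites=tuple(contributing)))
    nodes = {mid: "microbe" for mid in microbes}
    return InteractionNetwork(kind="species_species", nodes=nodes, edges=edges,
                              t_start=net.t_start, t_end=net.t_end)


def series_from_result(result: DfbaResult, which: str = "species_metabolite",
                       include_self_loops: bool = True) -> NetworkSeries:
    """Build the per-segment network series of a simulation result."""
    nets = []
    for k, seg in enumerate(result.segments):
        if which == "species_metabolite":
            nets.append(species_metabolite_network(seg, segment_index=k))
        elif which == "metabolite_metabolite":
            nets.append(metabolite_metabolite_network(
                seg, segment_index=k, include_self_loops=include_self_loops))
        elif which == "species_species":
            nets.append(species_species_network(
                species_metabolite_network(seg, segment_index=k)))
        else:
            raise ValueError(f"unknown network type {which!r}")
    return NetworkSeries(networks=nets)


def summarize_series(series: NetworkSeries) -> Tuple[InteractionNetwork,
                                                     InteractionNetwork]:
    """Duration-weighted mean and population-variance networks.

    Edges are keyed by (source, target, term_kind, mediator, microbe); an
    edge absent from a segment's network counts with weight 0 there.  The
    variance network carries the variance as weight and the sign of the
    time-averaged weight as raw_coeff (the colour convention of summary
    plots).
    """
    if not series.networks:
        raise ValueError("empty network series")
    durations = np.array([n.duration for n in series.networks], dtype=float)
    if np.any(durations <= 0):
        durations = np.maximum(durations, 1e-300)
    total = durations.sum()
    keys: Dict[Tuple, InteractionEdge] = {}
    weights: Dict[Tuple, np.ndarray] = {}
    for k, n in enumerate(series.networks):
        for e in n.edges:
            if e.key() not in weights:
                weights[e.key()] = np.zeros(len(series.networks))
                keys[e.key()] = e
            weights[e.key()][k] += e.weight
    nodes: Dict[str, str] = {}
    for n in series.networks:
        nodes.update(n.nodes)
    mean_edges, var_edges = [], []
    for key in sorted(weights, key=lambda k: tuple(str(v) for v in k)):
        w = weights[key]
        mean = float(np.sum(durations * w) / total)
        var = float(np.sum(durations * (w - mean) ** 2) / total)
        proto = keys[key]
        mean_edges.append(replace(proto, weight=mean, raw_coeff=mean,
                                  segment_index=-1))
        var_edges.append(replace(proto, weight=var, raw_coeff=float(np.sign(mean)),
                                 segment_index=-1))
    kind = series.networks[0].kind
    t0 = series.networks[0].t_start
    t1 = series.networks[-1].t_end
    return (InteractionNetwork(kind=kind, nodes=nodes, edges=mean_edges,
                               t_start=t0, t_end=t1),
            InteractionNetwork(kind=kind, nodes=nodes, edges=var_edges,
                               t_start=t0, t_end=t1))


def _edge_map(net: InteractionNetwork) -> Dict[Tuple, float]:
    out: Dict[Tuple, float] = {}
    for e in net.edges:
        out[e.key()] = out.get(e.key(), 0.0) + e.weight
    return out


def network_difference(net_a: InteractionNetwork, net_b: InteractionNetwork
                       ) -> Tuple[InteractionNetwork, List[Tuple]]:
    """Signed strength difference |w_A| - |w_B| over edges common to both.

    Edges present in only one network are excluded from the difference and
    returned separately as an exclusion report.
    """
    if net_a.kind != net_b.kind:
        raise ValueError(f"network type mismatch: {net_a.kind} vs {net_b.kind}")
    ma, mb = _edge_map(net_a), _edge_map(net_b)
    shared = sorted(set(ma) & set(mb), key=lambda k: tuple(str(v) for v in k))
    only = sorted((set(ma) | set(mb)) - set(shared),
                  key=lambda k: tuple(str(v) for v in k))
    edges = []
    for key in shared:
        signed = abs(ma[key]) - abs(mb[key])
        src, tgt, kind, mediator, microbe = key
        edges.append(InteractionEdge(
            source=src, target=tgt, weight=signed, raw_coeff=abs(signed),
            term_kind=kind, mediator=mediator, microbe=microbe))
    nodes = dict(net_a.nodes)
    nodes.update(net_b.nodes)
    return (InteractionNetwork(kind=net_a.kind, nodes=nodes, edges=edges),
            only)


def connection_shift(taxon: str, net_a: InteractionNetwork,
                     net_b: InteractionNetwork) -> float:
    """Mean strength change of a taxon's shared connections: mean(|w_A|-|w_B|).

    Raises ``ValueError`` if the taxon has no connection shared by both
    networks — an undefined shift is an error, never silently 0.
    """
    for net, name in ((net_a, "A"), (net_b, "B")):
        if taxon not in net.nodes:
            raise ValueError(f"taxon {taxon!r} absent from network {name}")
    ma = {k: w for k, w in _edge_map(net_a).items() if taxon in (k[0], k[1])}
    mb = {k: w for k, w in _edge_map(net_b).items() if taxon in (k[0], k[1])}
    shared = set(ma) & set(mb)
    if not shared:
        raise ValueError(f"taxon {taxon!r} has no connections shared by both networks")
    diffs = [abs(ma[k]) - abs(mb[k]) for k in sorted(
        shared, key=lambda k: tuple(str(v) for v in k))]
    return float(np.mean(diffs))


def fba_direct_network(models, env, y, weight_eps: float = WEIGHT_EPS
                       ) -> InteractionNetwork:
    """Baseline network read directly off one FBA solve per microbe.

    Microbe -> metabolite edges weighted by -(exchange rate) (consumption
    negative), and a marker edge metabolite -> microbe (weight +1) for every
    consumed metabolite — the crude assumption that whatever is consumed
    affects growth.  Unlike the segment networks, this cannot distinguish
    rate-limiting metabolites, so it typically carries many more
    metabolite -> microbe edges.
    """
    from .dynamics import align_environment  # local import to avoid cycle
    from .lp import assemble_lp, parsimonious_refine, solve_fba

    models, env = align_environment(models, env)
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    nodes = {m.id: "microbe" for m in models}
    nodes.update({met: "metabolite" for met in env.metabolite_ids})
    edges: List[InteractionEdge] = []
    for model in models:
        system = assemble_lp(model, env)
        sol = solve_fba(system, y)
        if not sol.optimal:
            continue
        sol = parsimonious_refine(system, y, sol)
        for l, met in enumerate(env.metabolite_ids):
            v = float(sol.exchange_rates[l])
            if abs(v) < weight_eps:
                continue
            edges.append(InteractionEdge(
                source=model.id, target=met, weight=-v, raw_coeff=v,
                term_kind="flux", microbe=model.id))
            if v > 0:  # consumed
                edges.append(InteractionEdge(
                    source=met, target=model.id, weight=1.0, raw_coeff=1.0,
                    term_kind="consumed_marker", microbe=model.id))
    return InteractionNetwork(kind="fba_direct", nodes=nodes, edges=edges)


def candidate_mediators(sm_net: InteractionNetwork, microbe_i: str,
                        microbe_j: str, required_sign: int) -> List[Tuple[str, float]]:
    """Metabolites mediating an i -> j interaction of the required sign.

    Returns ``(metabolite, path_product)`` pairs with
    sign(w_il * w_lj) == required_sign, strongest first.
    """
    for mid in (microbe_i, microbe_j):
        if mid not in sm_net.nodes or sm_net.nodes[mid] != "microbe":
            raise ValueError(f"unknown microbe id {mid!r}")
    w_out: Dict[str, float] = {}
    w_in: Dict[str, float] = {}
    for e in sm_net.edges:
        if e.term_kind == "growth" and e.target == microbe_j:
            w_in[e.source] = w_in.get(e.source, 0.0) + e.weight
        elif e.term_kind != "growth" and e.source == microbe_i:
            w_out[e.target] = w_out.get(e.target, 0.0) + e.weight
    out = []
    for met in sorted(set(w_out) & set(w_in)):
        prod = w_out[met] * w_in[met]
        if prod != 0.0 and np.sign(prod) == required_sign:
            out.append((met, prod))
    out.sort(key=lambda t: (-abs(t[1]), t[0]))
    return out


def significant_metabolites(result: DfbaResult, threshold: Optional[float] = None,
                            floor_eps: float = 1e-9) -> Dict[str, List[str]]:
    """Metabolites whose relative change over the run exceeds the threshold.

    Relative change is |y(t_end) - y(0)| / max(y(0), floor_eps); the default
    threshold is 1% .  Returns ``{"consumed": [...], "produced": [...]}``.
    """
    if result.times.size == 0:
        raise ValueError("empty trajectory")
    if threshold is None:
        threshold = 0.01
    y0 = result.y[0]
    y1 = result.y[-1]
    consumed, produced = [], []
    for j, met in enumerate(result.metabolite_ids):
        rel = abs(y1[j] - y0[j]) / max(y0[j], floor_eps)
        if rel > threshold:
            (consumed if y1[j] < y0[j] else produced).append(met)
    return {"consumed": consumed, "produced": produced}
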