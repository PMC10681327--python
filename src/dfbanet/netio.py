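"""Network, trajectory and transition writers (TSV/CSV/GraphML/JSON).

All floating-point output is printed with 9 significant digits and fixed
column order so that re-running an identical configuration reproduces
byte-identical files.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from .dynamics import DfbaResult
from .networks import InteractionEdge, InteractionNetwork

__all__ = ["write_network", "read_network", "to_networkx", "from_networkx",
           "write_trajectory", "write_transitions", "write_segments"]

EDGE_COLUMNS = ["source", "target", "weight", "raw_coeff", "term_kind",
                "mediator", "microbe", "segment", "t_start", "t_end"]


def _fmt(v: float) -> str:
    return "%.9g" % float(v)


def to_networkx(net: InteractionNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph(kind=net.kind, t_start=net.t_start, t_end=net.t_end)
    for node, typ in sorted(net.nodes.items()):
        g.add_node(node, node_type=typ)
    for e in net.edges:
        g.add_edge(e.source, e.target, weight=e.weight, raw_coeff=e.raw_coeff,
                   term_kind=e.term_kind, mediator=e.mediator or "",
                   microbe=e.microbe or "", segment=e.segment_index,
                   metabolites=";".join(e.metabolites))
    return g


def from_networkx(g: nx.MultiDiGraph) -> InteractionNetwork:
    nodes = {n: d.get("node_type", "metabolite") for n, d in g.nodes(data=True)}
    edges = []
    for u, v, d in g.edges(data=True):
        edges.append(InteractionEdge(
            source=u, target=v, weight=float(d["weight"]),
            raw_coeff=float(d.get("raw_coeff", d["weight"])),
            term_kind=d.get("term_kind", ""),
            mediator=d.get("mediator") or None,
            microbe=d.get("microbe") or None,
            segment_index=int(d.get("segment", -1)),
            metabolites=tuple(m for m in d.get("metabolites", "").split(";") if m)))
    return InteractionNetwork(
        kind=g.graph.get("kind", "species_metabolite"), nodes=nodes, edges=edges,
        t_start=float(g.graph.get("t_start", 0.0)),
        t_end=float(g.graph.get("t_end", 0.0)))


def write_network(net: InteractionNetwork, path: str, fmt: str = "tsv") -> None:
    """Write a network as a TSV edge list or GraphML."""
    if fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
        return
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(f"# kind={net.kind}\tt_start={_fmt(net.t_start)}"
                 f"\tt_end={_fmt(net.t_end)}\n")
        fh.write("\t".join(EDGE_COLUMNS + ["metabolites"]) + "\n")
        for e in net.edges:
            fh.write("\t".join([
                e.source, e.target, _fmt(e.weight), _fmt(e.raw_coeff),
                e.term_kind, e.mediator or "", e.microbe or "",
                str(e.segment_index), _fmt(net.t_start), _fmt(net.t_end),
                ";".join(e.metabolites)]) + "\n")


def read_network(path: str, fmt: str = "tsv",
                 node_types: Optional[Dict[str, str]] = None) -> InteractionNetwork:
    """Read a network written by :func:`write_network`.

    TSV files do not carry isolated nodes; node types are inferred from edge
    term kinds unless ``node_types`` is given.
    """
    if fmt == "graphml":
        return from_networkx(nx.read_graphml(str(path), force_multigraph=True))
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(item.split("=", 1) for item in header.lstrip("# ").split("\t"))
        cols = fh.readline().rstrip("\n").split("\t")
        edges = []
        for line in fh:
            vals = dict(zip(cols, line.rstrip("\n").split("\t")))
            edges.append(InteractionEdge(
                source=vals["source"], target=vals["target"],
                weight=float(vals["weight"]), raw_coeff=float(vals["raw_coeff"]),
                term_kind=vals["term_kind"], mediator=vals["mediator"] or None,
                microbe=vals["microbe"] or None,
                segment_index=int(vals["segment"]),
                metabolites=tuple(m for m in vals.get("metabolites", "").split(";") if m)))
    kind = meta.get("kind", "species_metabolite")
    nodes: Dict[str, str] = dict(node_types or {})
    for e in edges:
        if kind == "species_metabolite":
            if e.term_kind == "growth":
                nodes.setdefault(e.source, "metabolite")
                nodes.setdefault(e.target, "microbe")
            else:
                nodes.setdefault(e.source, "microbe")
                nodes.setdefault(e.target, "metabolite")
        elif kind == "metabolite_metabolite":
            nodes.setdefault(e.source, "metabolite")
            nodes.setdefault(e.target, "metabolite")
        elif kind == "fba_direct":
            mic = e.microbe
            for n in (e.source, e.target):
                nodes.setdefault(n, "microbe" if n == mic else "metabolite")
        else:
            nodes.setdefault(e.source, "microbe")
            nodes.setdefault(e.target, "microbe")
    return InteractionNetwork(
        kind=kind, nodes=nodes, edges=edges,
        t_start=float(meta.get("t_start", 0.0)),
        t_end=float(meta.get("t_end", 0.0)))


def write_trajectory(result: DfbaResult, path: str) -> None:
    cols = (["time"] + [f"x_{m}" for m in result.microbe_ids]
            + [f"y_{m}" for m in result.metabolite_ids])
    data = np.hstack([result.times[:, None], result.x, result.y])
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in data:
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def write_transitions(result: DfbaResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("time\tmicrobe\tconstraint\taction\n")
        for tr in result.transitions:
            fh.write("\t".join([
                _fmt(tr.time), ";".join(tr.microbe_ids),
                tr.violated_constraint, tr.action]) + "\n")


def write_segments(result: DfbaResult, path: str) -> None:
    """Per-segment JSON: interval, basis row indices/labels, coefficients."""
    out = []
    for k, seg in enumerate(result.segments):
        c = seg.coeffs
        rec = {
            "index": k,
            "t_start": float(seg.t_start),
            "t_end": float(seg.t_end),
            "bases": {},
            "intrinsic_growth": {mid: float(c.intrinsic_growth[i])
                                 for i, mid in enumerate(c.microbe_ids)},
            "growth_coeffs": {mid: {c.metabolite_ids[j]: float(a)
                                    for j, a in sorted(c.growth_coeffs[i].items())}
                              for i, mid in enumerate(c.microbe_ids)},
            "constant_exchange": {mid: {c.metabolite_ids[l]: float(v)
                                        for l, v in enumerate(c.constant_exchange[i])
                                        if v != 0.0}
                                  for i, mid in enumerate(c.microbe_ids)},
            "mediated_exchange": {
                mid: {f"{c.metabolite_ids[j]}->{c.metabolite_ids[l]}": float(b)
                      for (j, l), b in sorted(c.mediated_exchange[i].items())}
                for i, mid in enumerate(c.microbe_ids)},
        }
        for i, basis in enumerate(seg.bases):
            mid = c.microbe_ids[i]
            if basis is None:
                rec["bases"][mid] = None
            else:
                rec["bases"][mid] = {
                    "row_indices": list(basis.row_indices),
                    "row_labels": [r.label for r in basis.rows],
                }
        out.append(rec)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")
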