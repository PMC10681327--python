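"""End-to-end pipeline: simulate, build networks, emit the output bundle."""

from __future__ import annotations

import datetime
import json
import logging
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import fixtures as fx
from .bounds import BoundFunction
from .config import ConfigError, RunConfig
from .dynamics import DfbaResult, simulate_community
from .model import EnvironmentSpec, MetabolicModel
from .model_io import load_model
from .netio import (write_network, write_segments, write_trajectory,
                    write_transitions)
from .networks import (InteractionNetwork, NetworkSeries, connection_shift,
                       network_difference, series_from_result,
                       significant_metabolites, summarize_series)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "compare_runs", "assemble_community"]

_FIXTURES = {
    "monod_linear": lambda: _single(fx.monod_linear()),
    "capped_growth": lambda: _single(fx.capped_growth()),
    "diauxie": lambda: _single(fx.diauxie()),
    "crossfeed_pair": fx.crossfeed_pair,
    "competition_pair": fx.competition_pair,
}


def _single(t):
    model, env, x0 = t
    return [model], env, x0


def assemble_community(cfg: RunConfig
                       ) -> Tuple[List[MetabolicModel], EnvironmentSpec, np.ndarray]:
    """Resolve a RunConfig into (models, environment, initial biomass)."""
    if cfg.fixture is not None:
        if cfg.fixture not in _FIXTURES:
            raise ConfigError(f"unknown fixture {cfg.fixture!r}; "
                              f"choose from {sorted(_FIXTURES)}")
        models, env, x0 = _FIXTURES[cfg.fixture]()
    else:
        models = [load_model(m["path"], m.get("dialect", "json"))
                  for m in cfg.models]
        mets = list(cfg.metabolites)
        env = EnvironmentSpec(
            metabolite_ids=mets,
            initial_amounts=np.array([cfg.metabolites[m] for m in mets], float),
            inflow=np.array([cfg.inflow.get(m, 0.0) for m in mets], float),
            significance_threshold=cfg.significance_threshold,
        )
        x0 = np.array([cfg.biomass.get(m.id, 0.1) for m in models], float)
    if cfg.metabolites and cfg.fixture is not None:
        for met, v in cfg.metabolites.items():
            if met in env.metabolite_ids:
                env.initial_amounts[env.index(met)] = v
    for met, rate in cfg.inflow.items():
        if met in env.metabolite_ids:
            env.inflow[env.index(met)] = rate
    if cfg.biomass and cfg.fixture is not None:
        for i, m in enumerate(models):
            if m.id in cfg.biomass:
                x0[i] = cfg.biomass[m.id]
    for key, spec in cfg.bound_overrides.items():
        model_id, met = key.split(":", 1)
        for m in models:
            if m.id == model_id and met in m.exchange_metabolite_ids:
                j = m.exchange_metabolite_ids.index(met)
                m.exchange_upper[j] = BoundFunction.from_dict(spec)
    return models, env, x0


def run_pipeline(cfg: RunConfig, timestamp: bool = True) -> Dict:
    """Simulate and write the full output bundle; returns the manifest dict.

    Emitted files: trajectory.csv, transitions.tsv, segments.json, per-segment
    species-metabolite / metabolite-metabolite / species-species networks
    (TSV + GraphML), duration-weighted mean and variance summary networks,
    the time-averaged species-species network, significant-metabolite report,
    and manifest.json.
    """
    cfg.validate()
    models, env, x0 = assemble_community(cfg)
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    result = simulate_community(models, env, x0, cfg.t_final,
                                config=cfg.sim_config())
    write_trajectory(result, os.path.join(out, "trajectory.csv"))
    write_transitions(result, os.path.join(out, "transitions.tsv"))
    write_segments(result, os.path.join(out, "segments.json"))

    files = ["trajectory.csv", "transitions.tsv", "segments.json"]
    if result.segments and len(models) > 0:
        for which, tag in [("species_metabolite", "sm"),
                           ("metabolite_metabolite", "mm"),
                           ("species_species", "ss")]:
            series = series_from_result(result, which,
                                        include_self_loops=cfg.include_self_loops)
            for k, net in enumerate(series.networks):
                base = f"{tag}_segment{k}"
                write_network(net, os.path.join(out, base + ".tsv"), "tsv")
                write_network(net, os.path.join(out, base + ".graphml"), "graphml")
                files += [base + ".tsv", base + ".graphml"]
            mean, var = summarize_series(series)
            for net, base in [(mean, f"{tag}_mean"), (var, f"{tag}_variance")]:
                write_network(net, os.path.join(out, base + ".tsv"), "tsv")
                files.append(base + ".tsv")
    else:
        logger.warning("no segments/microbes: writing trajectory only")

    sig = significant_metabolites(result, cfg.significance_threshold)
    with open(os.path.join(out, "significant_metabolites.json"), "w") as fh:
        json.dump(sig, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files.append("significant_metabolites.json")

    from . import __version__
    manifest = {
        "version": __version__,
        "status": result.status,
        "n_segments": len(result.segments),
        "segment_table": [
            {"index": k, "t_start": float(s.t_start), "t_end": float(s.t_end)}
            for k, s in enumerate(result.segments)],
        "transitions": len(result.transitions),
        "microbes": result.microbe_ids,
        "metabolites": result.metabolite_ids,
        "files": files,
        "config": {
            "fixture": cfg.fixture, "t_final": cfg.t_final,
            "refine": cfg.refine,
            "include_self_loops": cfg.include_self_loops,
            "significance_threshold": cfg.significance_threshold,
        },
    }
    if timestamp:
        manifest["timestamp"] = datetime.datetime.now().isoformat()
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def compare_runs(result_a: DfbaResult, result_b: DfbaResult,
                 taxa: Optional[Sequence[str]] = None) -> Dict:
    """Difference of time-averaged species-metabolite networks of two runs.

    Returns the shared-edge signed differences, the non-shared edge report,
    and the per-taxon mean connection shift (|w_A| - |w_B| averaged over
    shared connections).
    """
    mean_a, _ = summarize_series(series_from_result(result_a, "species_metabolite"))
    mean_b, _ = summarize_series(series_from_result(result_b, "species_metabolite"))
    diff, only = network_difference(mean_a, mean_b)
    if taxa is None:
        taxa = sorted(set(result_a.microbe_ids) & set(result_b.microbe_ids))
    shifts = {}
    for taxon in taxa:
        if taxon not in mean_a.nodes or taxon not in mean_b.nodes:
            raise ValueError(f"taxon {taxon!r} absent from one of the runs")
        shifts[taxon] = connection_shift(taxon, mean_a, mean_b)
    return {
        "difference_edges": [
            {"source": e.source, "target": e.target,
             "signed_difference": e.weight, "magnitude": e.raw_coeff,
             "term_kind": e.term_kind, "mediator": e.mediator}
            for e in diff.edges],
        "non_shared_edges": [list(map(str, key)) for key in only],
        "connection_shift": shifts,
    }
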