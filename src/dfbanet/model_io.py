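"""Model readers/writers: a full-fidelity JSON dialect and SBML L3 + FBC.

The JSON dialect stores everything the in-memory model holds, including the
metabolite-dependent uptake-bound kinetics, as a documented schema (see
README).  SBML carries the internal stoichiometry, constant flux bounds and
objective through standard L3/FBC constructs; environmental metabolites
appear as boundary-condition species.  SBML has no field for kinetic flux
bounds, so the exchange block (rows, constant lower bounds, bound-function
kinetics) is mirrored verbatim in a package annotation on the model; a
reader that ignores the annotation still sees a valid FBA model.
"""

from __future__ import annotations

import json
import logging
import re
from typing import List, Optional
from xml.sax.saxutils import escape, unescape

import numpy as np

from .bounds import BoundFunction
from .model import MetabolicModel, ModelValidationError

logger = logging.getLogger(__name__)

__all__ = ["load_model", "write_model"]

_ANNOT_NS = "https://dfbanet.readthedocs.io/exchange"
_INF = float("inf")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    def num(v: float):
        if v == _INF:
            return "inf"
        if v == -_INF:
            return "-inf"
        return v

    internal_triplets = [
        [model.internal_metabolite_ids[g], model.reaction_ids[r],
         float(model.internal_stoich[g, r])]
        for g in range(len(model.internal_metabolite_ids))
        for r in range(model.n_reactions)
        if model.internal_stoich[g, r] != 0.0
    ]
    exchange = []
    for j, met in enumerate(model.exchange_metabolite_ids):
        row = model.exchange_stoich[j, :]
        exchange.append({
            "metabolite": met,
            "lower": num(float(model.exchange_lower[j])),
            "bound": (model.exchange_upper[j].to_dict()
                      if model.exchange_upper[j] is not None else None),
            "stoichiometry": [[model.reaction_ids[r], float(row[r])]
                              for r in range(model.n_reactions) if row[r] != 0.0],
        })
    return {
        "id": model.id,
        "reactions": [
            {"id": rid,
             "lower": num(float(model.lower_flux[r])),
             "upper": num(float(model.upper_flux[r])),
             "objective": float(model.objective[r])}
            for r, rid in enumerate(model.reaction_ids)
        ],
        "internal_metabolites": list(model.internal_metabolite_ids),
        "internal_stoichiometry": internal_triplets,
        "exchange": exchange,
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    def num(v):
        if v == "inf":
            return _INF
        if v == "-inf":
            return -_INF
        return float(v)

    rids = [r["id"] for r in d["reactions"]]
    ridx = {rid: k for k, rid in enumerate(rids)}
    n = len(rids)
    imets = list(d["internal_metabolites"])
    gidx = {m: k for k, m in enumerate(imets)}
    internal = np.zeros((len(imets), n))
    for met, rid, coeff in d["internal_stoichiometry"]:
        internal[gidx[met], ridx[rid]] = coeff
    ex_ids, ex_lower, ex_upper = [], [], []
    ex = np.zeros((len(d["exchange"]), n))
    for j, rec in enumerate(d["exchange"]):
        ex_ids.append(rec["metabolite"])
        ex_lower.append(num(rec["lower"]))
        ex_upper.append(BoundFunction.from_dict(rec["bound"])
                        if rec.get("bound") else None)
        for rid, coeff in rec["stoichiometry"]:
            ex[j, ridx[rid]] = coeff
    return MetabolicModel(
        id=d["id"],
        reaction_ids=rids,
        internal_metabolite_ids=imets,
        exchange_metabolite_ids=ex_ids,
        internal_stoich=internal,
        exchange_stoich=ex,
        objective=np.array([r["objective"] for r in d["reactions"]], float),
        lower_flux=np.array([num(r["lower"]) for r in d["reactions"]]),
        upper_flux=np.array([num(r["upper"]) for r in d["reactions"]]),
        exchange_lower=np.array(ex_lower),
        exchange_upper=ex_upper,
    )


# ---------------------------------------------------------------------------
# SBML (Level 3 + FBC)
# ---------------------------------------------------------------------------

def _exchange_annotation(model: MetabolicModel) -> str:
    payload = _model_to_dict(model)["exchange"]
    return (f'<dfbanet:exchange xmlns:dfbanet="{_ANNOT_NS}">'
            f"{escape(json.dumps(payload))}</dfbanet:exchange>")


def _sanitize(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", sid)


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.id))
    sbml_model.setName(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in ("c", "e"):
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(1.0)

    name_by_sid = {}
    for met in model.internal_metabolite_ids:
        sp = sbml_model.createSpecies()
        sid = "M_" + _sanitize(met)
        sp.setId(sid)
        sp.setName(met)
        sp.setCompartment("c")
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        name_by_sid[met] = sid
    for met in model.exchange_metabolite_ids:
        sp = sbml_model.createSpecies()
        sid = "E_" + _sanitize(met)
        sp.setId(sid)
        sp.setName(met)
        sp.setCompartment("e")
        sp.setBoundaryCondition(True)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        name_by_sid["env:" + met] = sid

    def bound_param(value: float, tag: str) -> str:
        pid = f"fb_{tag}"
        par = sbml_model.createParameter()
        par.setId(pid)
        par.setConstant(True)
        par.setValue(value if np.isfinite(value) else
                     (1e6 if value > 0 else -1e6))
        return pid

    for r, rid in enumerate(model.reaction_ids):
        rxn = sbml_model.createReaction()
        rxn.setId("R_" + _sanitize(rid))
        rxn.setName(rid)
        rxn.setReversible(bool(model.lower_flux[r] < 0))
        rxn.setFast(False)
        for g, met in enumerate(model.internal_metabolite_ids):
            coeff = model.internal_stoich[g, r]
            if coeff == 0:
                continue
            ref = rxn.createProduct() if coeff > 0 else rxn.createReactant()
            ref.setSpecies(name_by_sid[met])
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        for j, met in enumerate(model.exchange_metabolite_ids):
            gamma = model.exchange_stoich[j, r]
            if gamma == 0:
                continue
            # uptake (positive gamma) consumes the boundary species
            ref = rxn.createReactant() if gamma > 0 else rxn.createProduct()
            ref.setSpecies(name_by_sid["env:" + met])
            ref.setStoichiometry(abs(float(gamma)))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(model.lower_flux[r]), f"lo_{r}"))
        rplug.setUpperFluxBound(bound_param(float(model.upper_flux[r]), f"up_{r}"))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    for r, rid in enumerate(model.reaction_ids):
        if model.objective[r] != 0:
            fo = objective.createFluxObjective()
            fo.setReaction("R_" + _sanitize(rid))
            fo.setCoefficient(float(model.objective[r]))

    if any(fn is not None and not fn.is_constant for fn in model.exchange_upper):
        logger.warning(
            "SBML has no kinetic flux-bound field; storing uptake-bound "
            "kinetics in a package annotation")
    sbml_model.setAnnotation(_exchange_annotation(model))
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelValidationError(
            f"SBML parse failure: {doc.getErrorLog().toString()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: no model element")
    mplug = sbml_model.getPlugin("fbc")

    species = {}
    boundary = {}
    for k in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(k)
        name = sp.getName() or sp.getId()
        if sp.getBoundaryCondition():
            boundary[sp.getId()] = name
        else:
            species[sp.getId()] = name

    rids, lower, upper = [], [], []
    net_internal = []  # per reaction: {species_id: coeff}
    net_boundary = []
    params = {sbml_model.getParameter(k).getId(): sbml_model.getParameter(k).getValue()
              for k in range(sbml_model.getNumParameters())}
    for k in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(k)
        rids.append(rxn.getName() or rxn.getId())
        coeffs_i, coeffs_b = {}, {}
        for ref, sign in [(rxn.getReactant(i), -1.0) for i in range(rxn.getNumReactants())] + \
                         [(rxn.getProduct(i), 1.0) for i in range(rxn.getNumProducts())]:
            sid = ref.getSpecies()
            c = sign * ref.getStoichiometry()
            if sid in boundary:
                coeffs_b[sid] = coeffs_b.get(sid, 0.0) + c
            else:
                coeffs_i[sid] = coeffs_i.get(sid, 0.0) + c
        net_internal.append(coeffs_i)
        net_boundary.append(coeffs_b)
        rplug = rxn.getPlugin("fbc")
        lo = params.get(rplug.getLowerFluxBound(), -_INF) if rplug else -_INF
        up = params.get(rplug.getUpperFluxBound(), _INF) if rplug else _INF
        lower.append(-_INF if lo <= -1e6 else lo)
        upper.append(_INF if up >= 1e6 else up)

    n = len(rids)
    used = set()
    for coeffs in net_internal:
        used.update(coeffs)
    unreferenced = [s for s in species if s not in used]
    if unreferenced:
        logger.warning("dropping %d metabolite(s) not referenced by any reaction",
                       len(unreferenced))
    imet_sids = [s for s in species if s in used]
    imets = [species[s] for s in imet_sids]
    internal = np.zeros((len(imet_sids), n))
    for r, coeffs in enumerate(net_internal):
        for sid, c in coeffs.items():
            internal[imet_sids.index(sid), r] = c

    objective = np.zeros(n)
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        rid_by_sbml = {}
        for k in range(sbml_model.getNumReactions()):
            rxn = sbml_model.getReaction(k)
            rid_by_sbml[rxn.getId()] = k
        for k in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(k)
            objective[rid_by_sbml[fo.getReaction()]] = fo.getCoefficient()
    if not np.any(objective != 0):
        raise ModelValidationError(f"{path}: no objective")

    # exchange block: prefer the package annotation, else derive from
    # boundary-species stoichiometry with default kinetics
    annot = sbml_model.getAnnotationString() or ""
    match = re.search(
        r"<dfbanet:exchange[^>]*>(.*?)</dfbanet:exchange>", annot, re.S)
    ridx = {rid: k for k, rid in enumerate(rids)}
    if match:
        payload = json.loads(unescape(match.group(1).strip(),
                                      {"&quot;": '"', "&apos;": "'"}))
        ex_ids = [rec["metabolite"] for rec in payload]
        ex = np.zeros((len(payload), n))
        ex_lower, ex_upper = [], []
        for j, rec in enumerate(payload):
            ex_lower.append(-_INF if rec["lower"] == "-inf"
                            else (_INF if rec["lower"] == "inf" else float(rec["lower"])))
            ex_upper.append(BoundFunction.from_dict(rec["bound"])
                            if rec.get("bound") else None)
            for rid, coeff in rec["stoichiometry"]:
                ex[j, ridx[rid]] = coeff
        ex_lower = np.array(ex_lower)
    else:
        ex_ids = sorted(boundary, key=lambda s: boundary[s])
        ex = np.zeros((len(ex_ids), n))
        for r, coeffs in enumerate(net_boundary):
            for sid, c in coeffs.items():
                ex[ex_ids.index(sid), r] = -c  # uptake = -net production of boundary sp.
        ex_ids = [boundary[s] for s in ex_ids]
        ex_lower = np.full(len(ex_ids), -_INF)
        ex_upper = [None] * len(ex_ids)

    return MetabolicModel(
        id=sbml_model.getName() or sbml_model.getId(),
        reaction_ids=rids,
        internal_metabolite_ids=imets,
        exchange_metabolite_ids=ex_ids,
        internal_stoich=internal,
        exchange_stoich=ex,
        objective=objective,
        lower_flux=np.array(lower),
        upper_flux=np.array(upper),
        exchange_lower=ex_lower,
        exchange_upper=ex_upper,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def load_model(path: str, dialect: str = "json") -> MetabolicModel:
    """Read a metabolic model from ``path`` in the named dialect."""
    if dialect == "json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str, dialect: str = "json") -> None:
    """Write a metabolic model to ``path``; the output round-trips."""
    model.validate()
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
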