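"""Flux balance analysis as an explicit row-constraint system.

The FBA linear program

    max  gamma . psi
    s.t. G_int  psi  = 0                (internal steady state)
         c1 <= G_ex psi <= c2(y)        (exchange, bounded by availability)
         d1 <= psi <= d2                (constant flux bounds)

is assembled into an ordered list of scalar constraint rows.  The fixed,
deterministic row order (internal balances, then exchange lower/upper per
environment-metabolite order, then flux lower/upper per reaction order)
matters: it is the tie-break order for active-set basis selection, so it is
part of the reproducibility contract.

Rows whose right-hand side is infinite can never be active and are omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.optimize import linprog

from .bounds import BoundFunction
from .model import EnvironmentSpec, MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintRow",
    "ConstraintSystem",
    "FluxSolution",
    "SolverError",
    "assemble_lp",
    "solve_fba",
    "parsimonious_refine",
]

#: standard double-precision LP tolerances; overridable per call
FEASIBILITY_TOL = 1e-7
OPTIMALITY_TOL = 1e-7


class SolverError(RuntimeError):
    """The LP backend failed in a way that is not plain infeasibility."""


@dataclass(frozen=True)
class ConstraintRow:
    """One scalar constraint ``coeff . psi  (=|<=|>=)  rhs``.

    ``rhs_fn`` (a :class:`BoundFunction` of environment metabolite
    ``met_index``) and ``rhs_const`` are mutually exclusive.
    """

    coeff: np.ndarray
    kind: str  # "eq" | "upper" | "lower"
    rhs_const: float = 0.0
    rhs_fn: Optional[BoundFunction] = None
    met_index: int = -1  # environment metabolite index the rhs_fn reads
    source: str = "flux-bound"  # "internal" | "exchange" | "flux-bound"
    label: str = ""

    def rhs(self, y: np.ndarray) -> float:
        if self.rhs_fn is None:
            return self.rhs_const
        return self.rhs_fn(y[self.met_index])

    def rhs_derivative(self, y: np.ndarray, ydot: np.ndarray) -> float:
        """d(rhs)/dt along ydot."""
        if self.rhs_fn is None:
            return 0.0
        return self.rhs_fn.derivative(y[self.met_index]) * ydot[self.met_index]

    @property
    def is_functional(self) -> bool:
        return self.rhs_fn is not None and not self.rhs_fn.is_constant


@dataclass
class ConstraintSystem:
    """Ordered stack of constraint rows for one organism's FBA problem."""

    model_id: str
    n_reactions: int
    objective: np.ndarray
    rows: List[ConstraintRow] = field(default_factory=list)
    exchange_stoich: np.ndarray = None  # kept for exchange-rate evaluation

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def residuals(self, psi: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Signed slack per row: >= 0 means satisfied (0 for equalities)."""
        out = np.empty(self.n_rows)
        for r, row in enumerate(self.rows):
            val = float(row.coeff @ psi)
            rhs = row.rhs(y)
            if row.kind == "eq":
                out[r] = -abs(val - rhs)
            elif row.kind == "upper":
                out[r] = rhs - val
            else:
                out[r] = val - rhs
        return out


def assemble_lp(model: MetabolicModel, env: EnvironmentSpec) -> ConstraintSystem:
    """Stack the model's constraints in the fixed deterministic order.

    The model must already be aligned to ``env`` (exchange rows indexed by
    ``env.metabolite_ids``).  Exchange upper rows reference the model's
    bound functions; all-zero exchange rows (metabolites the organism does
    not transport) produce no constraint.
    """
    if model.exchange_metabolite_ids != env.metabolite_ids:
        raise ValueError(
            f"model {model.id} is not aligned to the environment; "
            "call align_environment first"
        )
    rows: List[ConstraintRow] = []
    for g, met in enumerate(model.internal_metabolite_ids):
        rows.append(
            ConstraintRow(
                coeff=model.internal_stoich[g, :].copy(),
                kind="eq",
                rhs_const=0.0,
                source="internal",
                label=f"balance {met}",
            )
        )
    for j, met in enumerate(env.metabolite_ids):
        coeff = model.exchange_stoich[j, :]
        if not np.any(coeff != 0):
            continue
        if np.isfinite(model.exchange_lower[j]):
            rows.append(
                ConstraintRow(
                    coeff=coeff.copy(),
                    kind="lower",
                    rhs_const=float(model.exchange_lower[j]),
                    met_index=j,
                    source="exchange",
                    label=f"lower bound, {met} exchange",
                )
            )
        fn = model.exchange_bound(j)
        rows.append(
            ConstraintRow(
                coeff=coeff.copy(),
                kind="upper",
                rhs_fn=fn,
                met_index=j,
                source="exchange",
                label=f"upper bound, {met} uptake",
            )
        )
    for r, rid in enumerate(model.reaction_ids):
        e = np.zeros(model.n_reactions)
        e[r] = 1.0
        if np.isfinite(model.lower_flux[r]):
            rows.append(
                ConstraintRow(coeff=e, kind="lower", rhs_const=float(model.lower_flux[r]),
                              source="flux-bound", label=f"lower bound, flux {rid}")
            )
        if np.isfinite(model.upper_flux[r]):
            rows.append(
                ConstraintRow(coeff=e.copy(), kind="upper", rhs_const=float(model.upper_flux[r]),
                              source="flux-bound", label=f"upper bound, flux {rid}")
            )
    return ConstraintSystem(
        model_id=model.id,
        n_reactions=model.n_reactions,
        objective=model.objective.copy(),
        rows=rows,
        exchange_stoich=model.exchange_stoich.copy(),
    )


@dataclass
class FluxSolution:
    """An FBA solve result: fluxes psi, growth rate, exchange rates."""

    fluxes: np.ndarray
    objective_value: float
    exchange_rates: np.ndarray
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _linprog_matrices(system: ConstraintSystem, y: np.ndarray):
    """Split rows into (A_eq, b_eq, A_ub, b_ub) with rhs evaluated at y."""
    a_eq, b_eq, a_ub, b_ub = [], [], [], []
    for row in system.rows:
        rhs = row.rhs(y)
        if row.kind == "eq":
            a_eq.append(row.coeff)
            b_eq.append(rhs)
        elif row.kind == "upper":
            a_ub.append(row.coeff)
            b_ub.append(rhs)
        else:
            a_ub.append(-row.coeff)
            b_ub.append(-rhs)
    n = system.n_reactions
    A_eq = np.array(a_eq) if a_eq else None
    A_ub = np.array(a_ub) if a_ub else None
    return (A_eq, np.array(b_eq) if a_eq else None,
            A_ub, np.array(b_ub) if a_ub else None, n)


def solve_fba(
    system: ConstraintSystem,
    y: np.ndarray,
    objective: Optional[np.ndarray] = None,
) -> FluxSolution:
    """Maximize ``objective . psi`` subject to the constraint system at y.

    Negative entries of y are clipped to 0 (with a warning) before the bound
    functions are evaluated.  Solved with HiGHS dual simplex so the returned
    point is a vertex of the feasible polytope.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        logger.warning("solve_fba: clipping %d negative metabolite value(s) to 0",
                       int(np.sum(y < 0)))
        y = np.maximum(y, 0.0)
    gamma = system.objective if objective is None else np.asarray(objective, float)
    A_eq, b_eq, A_ub, b_ub, n = _linprog_matrices(system, y)
    res = linprog(
        -gamma, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=[(None, None)] * n, method="highs-ds",
    )
    if res.status == 0:
        psi = np.asarray(res.x)
        return FluxSolution(
            fluxes=psi,
            objective_value=float(gamma @ psi),
            exchange_rates=system.exchange_stoich @ psi,
            status="optimal",
        )
    if res.status == 2:
        return FluxSolution(np.zeros(n), 0.0,
                            np.zeros(system.exchange_stoich.shape[0]), "infeasible")
    if res.status == 3:
        return FluxSolution(np.zeros(n), np.inf,
                            np.zeros(system.exchange_stoich.shape[0]), "unbounded")
    raise SolverError(f"LP backend failure (status {res.status}): {res.message}")


def parsimonious_refine(
    system: ConstraintSystem,
    y: np.ndarray,
    solution: FluxSolution,
    optimality_tol: float = OPTIMALITY_TOL,
) -> FluxSolution:
    """Among optimal flux vectors, minimize total flux sum(|psi|).

    The growth objective is fixed at its optimum and sum(|psi|) is minimized
    via the standard variable splitting psi = p - q with p, q >= 0, keeping
    the refinement a pure LP.  If the secondary LP fails, the input solution
    is returned unchanged with a warning.
    """
    if not solution.optimal:
        raise ValueError("parsimonious_refine requires an optimal solution")
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    A_eq, b_eq, A_ub, b_ub, n = _linprog_matrices(system, y)

    def split(a):
        return None if a is None else np.hstack([a, -a])

    gamma_row = np.hstack([system.objective, -system.objective])
    if A_eq is None:
        A_eq2 = gamma_row[None, :]
        b_eq2 = np.array([solution.objective_value])
    else:
        A_eq2 = np.vstack([split(A_eq), gamma_row])
        b_eq2 = np.append(b_eq, solution.objective_value)
    res = linprog(
        np.ones(2 * n),
        A_ub=split(A_ub), b_ub=b_ub, A_eq=A_eq2, b_eq=b_eq2,
        bounds=[(0, None)] * (2 * n), method="highs-ds",
    )
    if res.status != 0:
        logger.warning("parsimonious refinement LP status %d; keeping original solution",
                       res.status)
        return solution
    psi = res.x[:n] - res.x[n:]
    obj = float(system.objective @ psi)
    if abs(obj - solution.objective_value) > max(
        optimality_tol, optimality_tol * abs(solution.objective_value)
    ):
        logger.warning("refined objective drifted; keeping original solution")
        return solution
    return FluxSolution(
        fluxes=psi,
        objective_value=obj,
        exchange_rates=system.exchange_stoich @ psi,
        status="optimal",
    )
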