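"""Active-constraint bases for flux balance optima.

By the fundamental theorem of linear programming, an optimal FBA solution
can be written as the solution of a square invertible subsystem of the
problem constraints: B psi = cbar(y), where B stacks the coefficient rows of
an active set and cbar their right-hand sides.  As the metabolite-dependent
bounds c2(y) vary in time, the same B keeps producing the optimal fluxes for
a while — so a single factorization replaces repeated optimization.

The basis here is an ACTIVE-SET basis (rows drawn from the explicit
constraint stack), not a solver-internal simplex basis; degeneracy is
resolved by a Bland-style lowest-row-index preference so that identical
inputs always yield the identical basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .lp import ConstraintSystem, FluxSolution, FEASIBILITY_TOL

__all__ = ["Basis", "DegenerateBasisError", "extract_basis", "basis_solve",
           "enumerate_optimal_bases"]

ACTIVE_TOL = 1e-7
COND_MAX = 1e12


class DegenerateBasisError(RuntimeError):
    """No invertible active-row basis could be completed."""


@dataclass
class Basis:
    """A square invertible active subsystem B psi = cbar(y).

    ``row_indices`` index into ``system.rows`` in increasing order; the
    right-hand sides cbar are re-evaluated at the current metabolite vector
    on every solve, which is what makes the basis track the dynamics.
    """

    system: ConstraintSystem
    row_indices: Tuple[int, ...]
    matrix: np.ndarray
    lu: tuple
    condition: float

    @property
    def rows(self):
        return [self.system.rows[i] for i in self.row_indices]

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return np.array([row.rhs(y) for row in self.rows])

    def rhs_derivative(self, y: np.ndarray, ydot: np.ndarray) -> np.ndarray:
        return np.array([row.rhs_derivative(y, ydot) for row in self.rows])

    def solve(self, y: np.ndarray) -> np.ndarray:
        return lu_solve(self.lu, self.rhs(y))

    def solve_transposed(self, v: np.ndarray) -> np.ndarray:
        """Solve B^T z = v (for objective/exchange row functionals)."""
        return lu_solve(self.lu, v, trans=1)

    @property
    def nonbasic_indices(self) -> Tuple[int, ...]:
        basic = set(self.row_indices)
        return tuple(i for i in range(self.system.n_rows) if i not in basic)


def basis_solve(basis: Basis, y: np.ndarray) -> np.ndarray:
    """psi = B^-1 cbar(y); no feasibility check (that is the event monitor's job)."""
    return basis.solve(np.asarray(y, dtype=float))


def _make_basis(system: ConstraintSystem, indices: Sequence[int]) -> Optional[Basis]:
    mat = np.array([system.rows[i].coeff for i in indices])
    if mat.shape[0] != mat.shape[1]:
        return None
    try:
        cond = np.linalg.cond(mat)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(cond) or cond > COND_MAX:
        return None
    lu = lu_factor(mat)
    return Basis(system=system, row_indices=tuple(indices), matrix=mat, lu=lu,
                 condition=cond)


def _active_indices(system: ConstraintSystem, psi: np.ndarray, y: np.ndarray,
                    active_tol: float) -> List[int]:
    res = system.residuals(psi, y)
    return [i for i in range(system.n_rows) if abs(res[i]) <= active_tol]


def extract_basis(
    system: ConstraintSystem,
    y: np.ndarray,
    solution: FluxSolution,
    active_tol: float = ACTIVE_TOL,
    feasibility_tol: float = FEASIBILITY_TOL,
) -> Basis:
    """Build the lowest-index invertible basis for an optimal vertex.

    Greedily scans rows in the fixed stack order, keeping every active row
    that increases the rank, until n_reactions independent rows are found
    (equality rows come first in the stack, so a maximal independent set of
    them is always included).  The deterministic scan is the Bland-style
    tie-break that makes degenerate vertices reproducible.
    """
    if not solution.optimal:
        raise ValueError("extract_basis requires an optimal solution")
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    psi = solution.fluxes
    n = system.n_reactions
    active = _active_indices(system, psi, y, active_tol)
    chosen: List[int] = []
    stack = np.zeros((0, n))
    for i in active:
        cand = np.vstack([stack, system.rows[i].coeff])
        if np.linalg.matrix_rank(cand, tol=1e-10) > stack.shape[0]:
            stack = cand
            chosen.append(i)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise DegenerateBasisError(
            f"{system.model_id}: only {len(chosen)} independent active rows "
            f"for {n} reactions; active rows: "
            + ", ".join(system.rows[i].label for i in active)
        )
    basis = _make_basis(system, chosen)
    if basis is None:
        raise DegenerateBasisError(
            f"{system.model_id}: active-row basis is numerically singular"
        )
    check = basis.solve(y)
    if np.max(np.abs(check - psi)) > max(1e2 * feasibility_tol,
                                         feasibility_tol * np.max(np.abs(psi) + 1)):
        raise DegenerateBasisError(
            f"{system.model_id}: basis solve does not reproduce the LP solution"
        )
    return basis


def enumerate_optimal_bases(
    system: ConstraintSystem,
    y: np.ndarray,
    solution: FluxSolution,
    active_tol: float = ACTIVE_TOL,
    max_candidates: int = 5000,
) -> List[Basis]:
    """All invertible active-row bases reproducing the optimal vertex.

    Every candidate contains the maximal independent set of equality rows
    (internal balances must always hold) and is completed with active bound
    rows.  Candidates are ordered by their row-index tuples (lowest first),
    which is the deterministic preference order.  At a non-degenerate vertex
    the list has exactly one element.
    """
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    psi = solution.fluxes
    n = system.n_reactions
    active = _active_indices(system, psi, y, active_tol)
    eq_rows = [i for i in active if system.rows[i].kind == "eq"]
    bound_rows = [i for i in active if system.rows[i].kind != "eq"]

    # maximal independent equality subset, lowest-index preference
    eq_core: List[int] = []
    stack = np.zeros((0, n))
    for i in eq_rows:
        cand = np.vstack([stack, system.rows[i].coeff])
        if np.linalg.matrix_rank(cand, tol=1e-10) > stack.shape[0]:
            stack = cand
            eq_core.append(i)

    need = n - len(eq_core)
    if need < 0:
        raise DegenerateBasisError(f"{system.model_id}: more equalities than reactions")
    out: List[Basis] = []
    count = 0
    for combo in combinations(bound_rows, need):
        count += 1
        if count > max_candidates:
            break
        idx = sorted(eq_core + list(combo))
        basis = _make_basis(system, idx)
        if basis is None:
            continue
        check = basis.solve(y)
        if np.max(np.abs(check - psi)) <= max(1e-6, 1e-8 * np.max(np.abs(psi) + 1)):
            out.append(basis)
    if not out:
        # fall back to the greedy deterministic basis
        out = [extract_basis(system, y, solution, active_tol=active_tol)]
    return out
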