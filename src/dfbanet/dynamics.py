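"""Basis-tracked dynamic FBA as a sequence of smooth ODE segments.

Community dynamic FBA couples per-organism flux optima to a shared
metabolite pool:

    dx_i/dt = x_i (gamma_i . psi_i)
    dy/dt   = phi - sum_i x_i  G*_i psi_i

with psi_i the organism's FBA optimum at the current environment y.  Holding
each organism's active-constraint basis fixed, psi_i = B_i^-1 cbar_i(y) is a
smooth function of y, so the whole system is a smooth ODE — until the basis
solution stops obeying some non-basic constraint, at which point new bases
are selected and a new segment begins.

Within a segment the right-hand side takes the bilinear form

    dx_i/dt = x_i (C_i + sum_j a_ij c2_ij(y_j))
    dy_l/dt = phi_l - sum_i x_i (D_il + sum_j b_ijl c2_ij(y_j))

whose constant coefficients (C, a, D, b) are exactly the edge weights of the
interaction networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .basis import (Basis, DegenerateBasisError, enumerate_optimal_bases,
                    extract_basis)
from .lp import (ConstraintSystem, FluxSolution, assemble_lp,
                 parsimonious_refine, solve_fba)
from .model import CommunityState, EnvironmentSpec, MetabolicModel, align_environment

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SegmentCoefficients",
    "ODESegment",
    "TransitionRecord",
    "DfbaResult",
    "forward_basis",
    "build_segment",
    "integrate_segment",
    "simulate_community",
    "direct_dfba_oracle",
]


@dataclass
class SimConfig:
    """Tolerances and policies for community simulation."""

    active_tol: float = 1e-7
    feasibility_tol: float = 1e-7
    deriv_tol: float = 1e-9
    time_tol: float = 1e-8
    rtol: float = 1e-10
    atol: float = 1e-12
    stationary_tol: float = 1e-6
    stationary_window: float = 0.1
    max_transitions: int = 500
    refine: bool = True           # parsimonious refinement at (re)starts
    max_step_halvings: int = 40
    protective_step: float = 1e-2


@dataclass
class SegmentCoefficients:
    """Constant ODE coefficients of one segment.

    ``intrinsic_growth[i]`` is C_i; ``growth_coeffs[i][j]`` is a_ij;
    ``constant_exchange[i][l]`` is D_il; ``mediated_exchange[i][(j, l)]`` is
    b_ijl, stored with the raw sign it carries inside the minus-summed
    metabolite equation.  Indices j, l are environment metabolite positions.
    """

    microbe_ids: List[str]
    metabolite_ids: List[str]
    intrinsic_growth: np.ndarray            # (p,)
    growth_coeffs: List[Dict[int, float]]   # per microbe: {j: a_ij}
    constant_exchange: np.ndarray           # (p, m): D_il
    mediated_exchange: List[Dict[Tuple[int, int], float]]  # {(j,l): b_ijl}
    bound_fns: List[Dict[int, object]]      # per microbe: {j: BoundFunction}


@dataclass
class ODESegment:
    """One smooth interval of the hybrid system."""

    t_start: float
    t_end: float
    bases: List[Optional[Basis]]
    coeffs: SegmentCoefficients
    systems: List[ConstraintSystem]
    inflow: np.ndarray

    def rhs(self, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        c = self.coeffs
        p = len(c.microbe_ids)
        m = len(c.metabolite_ids)
        yc = np.maximum(y, 0.0)
        fvals: List[Dict[int, float]] = []
        for i in range(p):
            fvals.append({j: fn(yc[j]) for j, fn in c.bound_fns[i].items()})
        dx = np.empty(p)
        dy = self.inflow.astype(float).copy()
        for i in range(p):
            growth = c.intrinsic_growth[i]
            for j, a in c.growth_coeffs[i].items():
                growth += a * fvals[i][j]
            dx[i] = x[i] * growth
            contrib = c.constant_exchange[i].copy()
            for (j, l), b in c.mediated_exchange[i].items():
                contrib[l] += b * fvals[i][j]
            dy -= x[i] * contrib
        return dx, dy


@dataclass
class TransitionRecord:
    """Why and when the hybrid system left a segment."""

    time: float
    microbe_ids: List[str]
    violated_constraint: str
    action: str  # "new_basis" | "step_reduced" | "initial"


@dataclass
class DfbaResult:
    """Ordered segments, sampled trajectory, transition log."""

    microbe_ids: List[str]
    metabolite_ids: List[str]
    segments: List[ODESegment]
    times: np.ndarray
    x: np.ndarray  # (nt, p)
    y: np.ndarray  # (nt, m)
    transitions: List[TransitionRecord]
    status: str  # "reached_t_final" | "stationary" | "failed"

    def state_at_end(self) -> CommunityState:
        return CommunityState(time=float(self.times[-1]), x=self.x[-1], y=self.y[-1])


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------

def build_segment(
    models: Sequence[MetabolicModel],
    bases: Sequence[Optional[Basis]],
    env: EnvironmentSpec,
    systems: Sequence[ConstraintSystem],
    t_start: float,
) -> ODESegment:
    """Compute the bilinear segment coefficients from the per-microbe bases.

    With z_i = B_i^-T gamma_i and M_i = G*_i B_i^-1:
      C_i  = sum over constant-rhs basis rows r of z_i[r] * rhs_r
      a_ij = sum over basis rows with a functional rhs on metabolite j of z_i[r]
      D_il = sum over constant-rhs rows of M_i[l, r] * rhs_r
      b_ijl= sum over functional rows on j of M_i[l, r]

    A microbe with no basis (infeasible LP: no growth, no exchange)
    contributes zeros.  Inflow enters the dynamics but never the coefficients.
    """
    m = len(env.metabolite_ids)
    p = len(models)
    intrinsic = np.zeros(p)
    growth_coeffs: List[Dict[int, float]] = [dict() for _ in range(p)]
    const_ex = np.zeros((p, m))
    mediated: List[Dict[Tuple[int, int], float]] = [dict() for _ in range(p)]
    bound_fns: List[Dict[int, object]] = [dict() for _ in range(p)]

    for i, (model, basis) in enumerate(zip(models, bases)):
        if basis is None:
            continue
        z = basis.solve_transposed(model.objective)
        M = np.array([basis.solve_transposed(model.exchange_stoich[l, :])
                      for l in range(m)])  # (m, n): M[l, r] = (G* B^-1)[l, r]
        for r, row in enumerate(basis.rows):
            if row.is_functional:
                j = row.met_index
                if j not in bound_fns[i]:
                    bound_fns[i][j] = row.rhs_fn
                growth_coeffs[i][j] = growth_coeffs[i].get(j, 0.0) + float(z[r])
                for l in range(m):
                    if M[l, r] != 0.0:
                        key = (j, l)
                        mediated[i][key] = mediated[i].get(key, 0.0) + float(M[l, r])
            else:
                rhs = row.rhs_const
                if rhs != 0.0:
                    intrinsic[i] += float(z[r]) * rhs
                    const_ex[i, :] += M[:, r] * rhs
    coeffs = SegmentCoefficients(
        microbe_ids=[mdl.id for mdl in models],
        metabolite_ids=list(env.metabolite_ids),
        intrinsic_growth=intrinsic,
        growth_coeffs=growth_coeffs,
        constant_exchange=const_ex,
        mediated_exchange=mediated,
        bound_fns=bound_fns,
    )
    return ODESegment(
        t_start=t_start,
        t_end=np.inf,
        bases=list(bases),
        coeffs=coeffs,
        systems=list(systems),
        inflow=env.inflow.copy(),
    )


# ---------------------------------------------------------------------------
# forward basis selection
# ---------------------------------------------------------------------------

def _slack_derivatives(basis: Basis, y: np.ndarray, ydot: np.ndarray,
                       zero_slack_idx: Sequence[int]) -> np.ndarray:
    """d(slack)/dt for the given non-basic rows under the basis dynamics.

    slack_r = rhs_r(y) - A_r psi(y) for uppers (mirrored for lowers), with
    psi(y) = B^-1 cbar(y); both terms are differentiated exactly through the
    bound functions.
    """
    system = basis.system
    psidot = np.linalg.solve(basis.matrix, basis.rhs_derivative(y, ydot))
    out = np.empty(len(zero_slack_idx))
    for k, ri in enumerate(zero_slack_idx):
        row = system.rows[ri]
        d_val = float(row.coeff @ psidot)
        d_rhs = row.rhs_derivative(y, ydot)
        if row.kind == "upper":
            out[k] = d_rhs - d_val
        elif row.kind == "lower":
            out[k] = d_val - d_rhs
        else:  # equality held outside the basis: need |A psi - rhs| stable
            out[k] = -abs(d_val - d_rhs)
    return out


def forward_basis(
    system: ConstraintSystem,
    y: np.ndarray,
    ydot_estimate: np.ndarray,
    candidates: Sequence[Basis],
    deriv_tol: float = 1e-9,
    active_tol: float = 1e-7,
) -> Optional[Basis]:
    """Pick the candidate basis that stays optimal longest, to first order.

    A candidate is admissible when every non-basic constraint that is
    currently tight keeps a slack derivative >= -deriv_tol under the induced
    dynamics (so the basis solution remains feasible — hence optimal — for
    small t > 0).  Among admissible candidates the one maximizing the
    minimum slack derivative is chosen; ties break to the lowest row-index
    tuple (candidates arrive in that order).  Returns None when no candidate
    is admissible, signalling that the caller must reduce the step.
    """
    if len(candidates) == 1:
        cand = candidates[0]
        psi = cand.solve(y)
        zero = [i for i in cand.nonbasic_indices
                if abs(system.residuals(psi, y)[i]) <= active_tol]
        if not zero:
            return cand
    best = None
    best_score = -np.inf
    for cand in candidates:
        psi = cand.solve(np.maximum(y, 0.0))
        res = system.residuals(psi, np.maximum(y, 0.0))
        zero = [i for i in cand.nonbasic_indices if res[i] <= active_tol]
        if not zero:
            score = np.inf
        else:
            derivs = _slack_derivatives(cand, np.maximum(y, 0.0), ydot_estimate, zero)
            if np.any(derivs < -deriv_tol):
                continue
            score = float(np.min(derivs))
        if score > best_score + 1e-15:
            best = cand
            best_score = score
    return best


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_segment(
    segment: ODESegment,
    state: CommunityState,
    t_max: float,
    config: SimConfig = SimConfig(),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Optional[Tuple[int, int, float]]]:
    """Integrate one smooth segment until a constraint event or t_max.

    Returns ``(times, x_samples, y_samples, event)`` where ``event`` is
    ``(microbe_index, row_index, slack)`` for the most violated monitored
    constraint at the event time (metabolite non-negativity is reported with
    ``row_index = -1 - metabolite_index``), or ``None`` if t_max was reached.

    The event function is the minimum over all monitored slacks (non-basic
    rows of every microbe's constraint stack, plus every y_j) shifted by
    active_tol; the integrator's dense output localizes the root to high
    precision.
    """
    p = len(state.x)
    m = len(state.y)
    if t_max <= state.time:
        return (np.array([state.time]), state.x[None, :].copy(),
                state.y[None, :].copy(), None)

    monitored: List[Tuple[int, int]] = []
    for i, basis in enumerate(segment.bases):
        if basis is None:
            continue
        monitored.extend((i, ri) for ri in basis.nonbasic_indices)

    def unpack(z):
        return z[:p], z[p:]

    def rhs(t, z):
        x, y = unpack(z)
        dx, dy = segment.rhs(x, y)
        return np.concatenate([dx, dy])

    def slacks(y):
        vals = []
        yc = np.maximum(y, 0.0)
        for i, ri in monitored:
            basis = segment.bases[i]
            psi = basis.solve(yc)
            row = segment.systems[i].rows[ri]
            val = float(row.coeff @ psi)
            rr = row.rhs(yc)
            if row.kind == "eq":
                vals.append(-abs(val - rr))
            elif row.kind == "upper":
                vals.append(rr - val)
            else:
                vals.append(val - rr)
        return vals

    def event(t, z):
        x, y = unpack(z)
        vals = slacks(y)
        vals.extend(y.tolist())
        return min(vals) + config.active_tol if vals else 1.0

    event.terminal = True
    event.direction = -1

    z0 = np.concatenate([state.x, state.y])
    sol = solve_ivp(
        rhs, (state.time, t_max), z0, method="RK45",
        rtol=config.rtol, atol=config.atol, events=event, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failure in segment: {sol.message}")
    times = sol.t
    xs = sol.y[:p, :].T
    ys = sol.y[p:, :].T
    ev = None
    if sol.t_events[0].size > 0:
        t_ev = float(sol.t_events[0][0])
        z_ev = sol.y_events[0][0]
        x_ev, y_ev = unpack(z_ev)
        vals = slacks(y_ev)
        all_vals = vals + y_ev.tolist()
        k = int(np.argmin(all_vals))
        if k < len(monitored):
            i, ri = monitored[k]
            ev = (i, ri, float(all_vals[k]))
        else:
            ev = (-1, -1 - (k - len(monitored)), float(all_vals[k]))
        if times[-1] < t_ev:
            times = np.append(times, t_ev)
            xs = np.vstack([xs, x_ev])
            ys = np.vstack([ys, y_ev])
        else:
            xs[-1], ys[-1] = x_ev, y_ev
    return times, xs, ys, ev


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _select_bases(
    models: Sequence[MetabolicModel],
    systems: Sequence[ConstraintSystem],
    env: EnvironmentSpec,
    x: np.ndarray,
    y: np.ndarray,
    config: SimConfig,
) -> Tuple[List[Optional[Basis]], List[FluxSolution], bool]:
    """Fresh FBA per microbe, parsimonious refine, forward-compatible basis.

    The community derivative estimate used for forward selection is
    assembled jointly from the fresh LP exchange rates of all microbes.
    Returns (bases, solutions, ok); ok=False means some microbe had no
    admissible forward basis (caller reduces the step).
    """
    yc = np.maximum(y, 0.0)
    solutions: List[FluxSolution] = []
    for system in systems:
        sol = solve_fba(system, yc)
        if sol.status == "unbounded":
            raise RuntimeError(f"unbounded FBA problem for {system.model_id}")
        if sol.optimal and config.refine:
            sol = parsimonious_refine(system, yc, sol)
        solutions.append(sol)

    ydot = env.inflow.astype(float).copy()
    for i, sol in enumerate(solutions):
        if sol.optimal:
            ydot -= x[i] * sol.exchange_rates

    bases: List[Optional[Basis]] = []
    ok = True
    for i, (system, sol) in enumerate(zip(systems, solutions)):
        if not sol.optimal:
            logger.warning("microbe %s: infeasible LP; zero flux for this segment",
                           system.model_id)
            bases.append(None)
            continue
        try:
            candidates = enumerate_optimal_bases(
                system, yc, sol, active_tol=config.active_tol)
        except DegenerateBasisError:
            # refined optimum may sit off a vertex of the original stack;
            # retry from the unrefined vertex solution
            raw = solve_fba(system, yc)
            candidates = enumerate_optimal_bases(
                system, yc, raw, active_tol=config.active_tol)
        chosen = forward_basis(system, yc, ydot, candidates,
                               deriv_tol=config.deriv_tol,
                               active_tol=config.active_tol)
        if chosen is None:
            ok = False
            chosen = candidates[0]
        bases.append(chosen)
    return bases, solutions, ok


def simulate_community(
    models: Sequence[MetabolicModel],
    env: EnvironmentSpec,
    x0: np.ndarray,
    t_final: float,
    config: SimConfig = SimConfig(),
) -> DfbaResult:
    """Run the full hybrid simulation from t = 0 to t_final.

    Loop: per-microbe FBA (with parsimonious refinement), forward-compatible
    basis selection, segment coefficient build, smooth integration to the
    first constraint event, transition record, repeat.  Terminates at
    t_final, or early with status "stationary" once every growth rate stays
    below ``stationary_tol`` for ``stationary_window`` hours.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    models, env = align_environment(models, env)
    systems = [assemble_lp(mdl, env) for mdl in models]
    p = len(models)
    x = np.asarray(x0, dtype=float).copy()
    y = env.initial_amounts.copy()
    t = 0.0

    segments: List[ODESegment] = []
    transitions: List[TransitionRecord] = []
    all_t = [np.array([0.0])]
    all_x = [x[None, :].copy()]
    all_y = [y[None, :].copy()]
    status = "reached_t_final"
    stationary_since: Optional[float] = None
    halvings = 0

    while t < t_final - config.time_tol:
        if len(transitions) >= config.max_transitions:
            status = "failed"
            logger.error("max_transitions (%d) exceeded at t=%.6g",
                         config.max_transitions, t)
            break
        bases, solutions, ok = _select_bases(models, systems, env, x, y, config)
        growth = np.array([s.objective_value if s.optimal else 0.0
                           for s in solutions])
        if np.all(np.abs(growth) < config.stationary_tol) and np.all(
                np.abs(env.inflow) < config.stationary_tol):
            if stationary_since is None:
                stationary_since = t
            elif t - stationary_since >= config.stationary_window:
                status = "stationary"
                break
        else:
            stationary_since = None

        if not ok:
            # no admissible forward basis: protective Euler step with fresh FBA
            if halvings >= config.max_step_halvings:
                status = "failed"
                logger.error("step reduction exhausted at t=%.6g", t)
                break
            delta = config.protective_step / (2 ** halvings)
            halvings += 1
            transitions.append(TransitionRecord(
                time=t, microbe_ids=[], violated_constraint="(none)",
                action="step_reduced"))
            dy = env.inflow.astype(float).copy()
            dx = np.zeros(p)
            for i, sol in enumerate(solutions):
                if sol.optimal:
                    dx[i] = x[i] * sol.objective_value
                    dy -= x[i] * sol.exchange_rates
            t = min(t + delta, t_final)
            x = np.maximum(x + delta * dx, 0.0)
            y = np.maximum(y + delta * dy, 0.0)
            all_t.append(np.array([t]))
            all_x.append(x[None, :].copy())
            all_y.append(y[None, :].copy())
            continue
        halvings = 0

        segment = build_segment(models, bases, env, systems, t)
        state = CommunityState(time=t, x=x, y=y)
        times, xs, ys, event = integrate_segment(segment, state, t_final, config)
        segment.t_end = float(times[-1])
        segments.append(segment)
        all_t.append(times[1:])
        all_x.append(xs[1:])
        all_y.append(ys[1:])
        t = float(times[-1])
        x = np.maximum(xs[-1].copy(), 0.0)
        y = ys[-1].copy()
        if event is None:
            break
        i, ri, _ = event
        if ri < 0:
            label = f"non-negativity, {env.metabolite_ids[-1 - ri]}"
            mids = []
        else:
            label = systems[i].rows[ri].label
            mids = [models[i].id]
        transitions.append(TransitionRecord(
            time=t, microbe_ids=mids, violated_constraint=label,
            action="new_basis"))

    times = np.concatenate(all_t)
    xs = np.vstack(all_x)
    ys = np.vstack(all_y)
    return DfbaResult(
        microbe_ids=[mdl.id for mdl in models],
        metabolite_ids=list(env.metabolite_ids),
        segments=segments,
        times=times,
        x=xs,
        y=ys,
        transitions=transitions,
        status=status,
    )


# ---------------------------------------------------------------------------
# direct repeated-optimization oracle
# ---------------------------------------------------------------------------

def direct_dfba_oracle(
    models: Sequence[MetabolicModel],
    env: EnvironmentSpec,
    x0: np.ndarray,
    t_final: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    refine: bool = True,
) -> DfbaResult:
    """Reference DFBA by re-solving every LP inside the ODE right-hand side.

    This is the conventional (slow) way to integrate dynamic FBA; it shares
    no code path with the basis-tracked integrator and serves as its
    independent cross-check.
    """
    models, env = align_environment(models, env)
    systems = [assemble_lp(mdl, env) for mdl in models]
    p = len(models)
    m = len(env.metabolite_ids)

    def rhs(t, z):
        x = z[:p]
        y = np.maximum(z[p:], 0.0)
        dx = np.zeros(p)
        dy = env.inflow.astype(float).copy()
        for i, system in enumerate(systems):
            sol = solve_fba(system, y)
            if not sol.optimal:
                continue
            if refine:
                sol = parsimonious_refine(system, y, sol)
            dx[i] = x[i] * sol.objective_value
            dy -= x[i] * sol.exchange_rates
        return np.concatenate([dx, dy])

    z0 = np.concatenate([np.asarray(x0, float), env.initial_amounts])
    sol = solve_ivp(rhs, (0.0, t_final), z0, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"direct oracle integration failed: {sol.message}")
    return DfbaResult(
        microbe_ids=[mdl.id for mdl in models],
        metabolite_ids=list(env.metabolite_ids),
        segments=[],
        times=sol.t,
        x=sol.y[:p, :].T,
        y=sol.y[p:, :].T,
        transitions=[],
        status="reached_t_final",
    )
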