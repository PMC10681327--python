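"""Segment coefficients, event detection, forward-basis choice, full runs."""

import numpy as np
import pytest

import dfbanet as dn
from dfbanet import fixtures as fx
from dfbanet.dynamics import SimConfig, _select_bases

from conftest import trajectory_rel_error


# -- segment coefficients ----------------------------------------------------

def test_monod_segment_coefficients(simulated):
    seg = simulated["monod_linear"].segments[0]
    c = seg.coeffs
    assert c.intrinsic_growth[0] == pytest.approx(0.0, abs=1e-12)
    assert c.growth_coeffs[0] == pytest.approx({0: 0.5})
    np.testing.assert_allclose(c.constant_exchange, 0.0, atol=1e-12)
    assert c.mediated_exchange[0] == pytest.approx({(0, 0): 1.0})


def test_capped_segment1_growth_is_intrinsic(simulated):
    c = simulated["capped_growth"].segments[0].coeffs
    assert c.intrinsic_growth[0] == pytest.approx(10.0)
    assert c.growth_coeffs[0] == {}
    assert c.constant_exchange[0, 0] == pytest.approx(20.0)
    assert c.mediated_exchange[0] == {}


def test_zero_microbe_community_inflow_only():
    env = dn.EnvironmentSpec(metabolite_ids=["s"],
                             initial_amounts=np.array([1.0]),
                             inflow=np.array([0.5]))
    res = dn.simulate_community([], env, np.array([]), t_final=2.0)
    assert res.y[-1, 0] == pytest.approx(1.0 + 0.5 * 2.0, rel=1e-8)


def test_segment_rhs_matches_basis_solve(simulated):
    """ODE-coefficient consistency: segment RHS == gamma.psi and G*.psi."""
    for name, res in simulated.items():
        for seg in res.segments:
            t0, t1 = seg.t_start, min(seg.t_end, res.times[-1])
            for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
                t = t0 + frac * (t1 - t0)
                k = np.searchsorted(res.times, t)
                x, y = res.x[k], np.maximum(res.y[k], 0.0)
                dx, dy = seg.rhs(x, y)
                dy_direct = seg.inflow.copy()
                for i, basis in enumerate(seg.bases):
                    if basis is None:
                        assert dx[i] == 0.0
                        continue
                    psi = dn.basis_solve(basis, y)
                    growth = float(seg.systems[i].objective @ psi)
                    assert dx[i] == pytest.approx(x[i] * growth, abs=1e-9)
                    dy_direct -= x[i] * (seg.systems[i].exchange_stoich @ psi)
                np.testing.assert_allclose(dy, dy_direct, atol=1e-9)


def test_segment_interior_states_remain_lp_optimal(simulated):
    """At interior times the basis solution has the fresh-LP objective."""
    for name, res in simulated.items():
        for seg in res.segments:
            t1 = min(seg.t_end, res.times[-1])
            for frac in (0.15, 0.4, 0.6, 0.8, 0.95):
                t = seg.t_start + frac * (t1 - seg.t_start)
                k = min(np.searchsorted(res.times, t), len(res.times) - 1)
                y = np.maximum(res.y[k], 0.0)
                for i, basis in enumerate(seg.bases):
                    if basis is None:
                        continue
                    psi = dn.basis_solve(basis, y)
                    fresh = dn.solve_fba(seg.systems[i], y)
                    assert seg.systems[i].objective @ psi == pytest.approx(
                        fresh.objective_value, abs=1e-6), (name, t)


# -- events ------------------------------------------------------------------

def test_capped_growth_event_time_analytic(simulated):
    res = simulated["capped_growth"]
    t_star = np.log(51.0) / 10.0
    assert len(res.transitions) == 1
    assert abs(res.transitions[0].time - t_star) < 1e-6
    assert "glucose uptake" in res.transitions[0].violated_constraint
    assert res.transitions[0].action == "new_basis"


def test_monod_no_event_and_conservation(simulated):
    res = simulated["monod_linear"]
    assert len(res.segments) == 1
    cons = res.x[:, 0] + res.y[:, 0] / 2.0
    assert np.max(np.abs(cons - cons[0])) < 1e-8


def test_integrate_empty_interval(simulated):
    res = simulated["monod_linear"]
    seg = res.segments[0]
    state = dn.CommunityState(time=1.0, x=np.array([0.2]), y=np.array([5.0]))
    times, xs, ys, event = dn.integrate_segment(seg, state, t_max=1.0)
    assert times.tolist() == [1.0]
    assert event is None


# -- forward-basis selection -------------------------------------------------

def test_forward_basis_picks_uptake_row_when_substrate_falls(capped):
    models, env, x0 = capped
    models, env = dn.align_environment(models, env)
    system = dn.assemble_lp(models[0], env)
    y = np.array([20.0])
    sol = dn.solve_fba(system, y)
    cands = dn.enumerate_optimal_bases(system, y, sol)
    assert len(cands) >= 2
    ydot = np.array([-1.0])  # glucose decreasing
    chosen = dn.forward_basis(system, y, ydot, cands)
    labels = [r.label for r in chosen.rows]
    assert "upper bound, glucose uptake" in labels
    assert "upper bound, flux g" not in labels


def test_forward_basis_single_candidate_passthrough(monod):
    models, env, _ = monod
    models, env = dn.align_environment(models, env)
    system = dn.assemble_lp(models[0], env)
    y = np.array([2.0])
    sol = dn.solve_fba(system, y)
    cands = dn.enumerate_optimal_bases(system, y, sol)
    assert len(cands) == 1
    chosen = dn.forward_basis(system, y, np.array([-0.1]), cands)
    assert chosen.row_indices == cands[0].row_indices


def test_forward_basis_none_when_substrate_rises(capped):
    """With glucose rising, the uptake-limited basis is not forward-feasible
    and the growth-cap basis is; selection must prefer the cap basis."""
    models, env, _ = capped
    models, env = dn.align_environment(models, env)
    system = dn.assemble_lp(models[0], env)
    y = np.array([20.0])
    sol = dn.solve_fba(system, y)
    cands = dn.enumerate_optimal_bases(system, y, sol)
    chosen = dn.forward_basis(system, y, np.array([+1.0]), cands)
    labels = [r.label for r in chosen.rows]
    assert "upper bound, flux g" in labels


# -- full simulation ---------------------------------------------------------

def test_capped_growth_two_segments_and_asymptote(simulated):
    res = simulated["capped_growth"]
    assert len(res.segments) == 2
    assert res.x[-1, 0] == pytest.approx(15.1, abs=1e-3)
    assert res.y[-1, 0] < 1e-2


def test_diauxie_at_least_two_segments_and_rewiring(simulated):
    res = simulated["diauxie"]
    assert len(res.segments) >= 2
    first = dn.species_metabolite_network(res.segments[0])
    later = dn.species_metabolite_network(res.segments[1])
    growth_first = [e for e in first.edges if e.term_kind == "growth"
                    and e.source == "glucose"]
    growth_later = [e for e in later.edges if e.term_kind == "growth"
                    and e.source == "glucose"]
    assert not growth_first  # glucose not yet rate-limiting
    assert growth_later


def test_diauxie_zero_capacity_no_growth():
    model, env, x0 = fx.diauxie(capacity=0.0)
    res = dn.simulate_community([model], env, x0, t_final=1.0)
    assert res.status in ("stationary", "reached_t_final")
    np.testing.assert_allclose(res.x[:, 0], x0[0], atol=1e-9)
    assert len(res.segments) <= 1


def test_zero_biomass_community_constant():
    model, env, x0 = fx.monod_linear()
    res = dn.simulate_community([model], env, np.array([0.0]), t_final=2.0)
    np.testing.assert_allclose(res.x, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.y[:, 0], env.initial_amounts[0], atol=1e-8)


def test_forward_invariance_on_fixtures_and_random(simulated):
    for name, res in simulated.items():
        assert res.x.min() >= -1e-7, name
        assert res.y.min() >= -1e-7, name
    for seed in range(20):
        models, env, x0 = fx.random_community(seed)
        res = dn.simulate_community(models, env, x0, t_final=2.0)
        assert res.x.min() >= -1e-7, seed
        assert res.y.min() >= -1e-7, seed


def test_reproducibility_bitwise(capped):
    models, env, x0 = capped
    r1 = dn.simulate_community(models, env, x0, t_final=5.0)
    r2 = dn.simulate_community(models, env, x0, t_final=5.0)
    assert len(r1.segments) == len(r2.segments)
    for s1, s2 in zip(r1.segments, r2.segments):
        assert [b.row_indices for b in s1.bases] == [b.row_indices for b in s2.bases]
    assert [t.time for t in r1.transitions] == [t.time for t in r2.transitions]
    np.testing.assert_array_equal(r1.times, r2.times)
    np.testing.assert_array_equal(r1.x, r2.x)


def test_t_final_must_be_positive(monod):
    models, env, x0 = monod
    with pytest.raises(ValueError):
        dn.simulate_community(models, env, x0, t_final=0.0)


# -- oracle cross-check ------------------------------------------------------

def test_oracle_equivalence_all_fixtures(simulated, oracle_runs):
    for name in simulated:
        err = trajectory_rel_error(simulated[name], oracle_runs[name])
        assert err < 1e-3, (name, err)


def test_oracle_detects_same_transition_region(oracle_runs):
    """Oracle growth rate drops from 10 near the analytic event time."""
    res = oracle_runs["capped_growth"]
    t_star = np.log(51.0) / 10.0
    growth = np.gradient(np.log(res.x[:, 0]), res.times)
    below = res.times[np.where(growth < 9.5)[0]]
    after_event = below[below > 0.1]
    assert after_event.size and abs(after_event[0] - t_star) < 0.05


def test_oracle_zero_biomass_identical_trajectories(monod):
    models, env, _ = monod
    res = dn.simulate_community(models, env, np.array([0.0]), t_final=1.0)
    orc = dn.direct_dfba_oracle(models, env, np.array([0.0]), t_final=1.0)
    assert trajectory_rel_error(res, orc) < 1e-9
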