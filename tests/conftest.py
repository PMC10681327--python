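import numpy as np
import pytest

import dfbanet as dn
from dfbanet import fixtures as fx


@pytest.fixture(scope="session")
def monod():
    model, env, x0 = fx.monod_linear()
    return [model], env, x0


@pytest.fixture(scope="session")
def capped():
    model, env, x0 = fx.capped_growth()
    return [model], env, x0


@pytest.fixture(scope="session")
def diauxie_fix():
    model, env, x0 = fx.diauxie()
    return [model], env, x0


@pytest.fixture(scope="session")
def crossfeed():
    return fx.crossfeed_pair()


@pytest.fixture(scope="session")
def competition():
    return fx.competition_pair()


@pytest.fixture(scope="session")
def all_fixture_communities(monod, capped, diauxie_fix, crossfeed, competition):
    return {
        "monod_linear": monod,
        "capped_growth": capped,
        "diauxie": diauxie_fix,
        "crossfeed_pair": crossfeed,
        "competition_pair": competition,
    }


@pytest.fixture(scope="session")
def simulated(all_fixture_communities):
    """Basis-tracked simulation of every fixture, shared across tests."""
    out = {}
    for name, (models, env, x0) in all_fixture_communities.items():
        out[name] = dn.simulate_community(models, env, x0, t_final=5.0)
    return out


@pytest.fixture(scope="session")
def oracle_runs(all_fixture_communities):
    """Direct repeated-LP integration of every fixture (the slow reference)."""
    out = {}
    for name, (models, env, x0) in all_fixture_communities.items():
        out[name] = dn.direct_dfba_oracle(models, env, x0, t_final=5.0)
    return out


def trajectory_rel_error(res_a, res_b, n_grid: int = 200) -> float:
    """Max state-normalized deviation between two trajectories."""
    t_end = min(res_a.times[-1], res_b.times[-1])
    grid = np.linspace(0.0, t_end, n_grid)
    za = np.hstack([res_a.x, res_a.y])
    zb = np.hstack([res_b.x, res_b.y])
    ia = np.array([np.interp(grid, res_a.times, za[:, k]) for k in range(za.shape[1])])
    ib = np.array([np.interp(grid, res_b.times, zb[:, k]) for k in range(zb.shape[1])])
    scale = np.maximum(np.max(np.abs(ia), axis=1), np.max(np.abs(ib), axis=1))
    scale = np.maximum(scale, 1e-9)
    return float(np.max(np.abs(ia - ib) / scale[:, None]))
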