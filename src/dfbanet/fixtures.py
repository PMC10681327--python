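"""Hand-constructed toy communities with pencil-and-paper dynamics.

Each fixture is small enough that its FBA vertices, basis matrices, ODE
coefficients and even event times can be derived by hand; the derivations
live in docs/methods.md and are frozen into the test suite.  Fixture
generation is deterministic and pure.  A separate seeded random-community
generator exists only for property tests.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .bounds import linear
from .model import EnvironmentSpec, MetabolicModel

__all__ = [
    "monod_linear",
    "capped_growth",
    "diauxie",
    "crossfeed_pair",
    "competition_pair",
    "futile_cycle",
    "random_community",
]

INF = np.inf


def monod_linear(kappa: float = 1.0, x0: float = 0.1, y0: float = 10.0
                 ) -> Tuple[MetabolicModel, EnvironmentSpec]:
    """One microbe, one substrate, linear uptake kinetics.

    Reactions (u, g): uptake and growth, coupled by the internal balance
    u - 2 g = 0 (yield one half).  Uptake is bounded by kappa * y.  With
    kappa = 1 the dynamics on the single segment are dx/dt = 0.5 x y,
    dy/dt = -x y, conserving x + y/2.
    """
    model = MetabolicModel(
        id="M",
        reaction_ids=["u", "g"],
        internal_metabolite_ids=["carbon_c"],
        exchange_metabolite_ids=["glucose"],
        internal_stoich=np.array([[1.0, -2.0]]),
        exchange_stoich=np.array([[1.0, 0.0]]),
        objective=np.array([0.0, 1.0]),
        lower_flux=np.array([0.0, 0.0]),
        upper_flux=np.array([INF, 1000.0]),
        exchange_lower=np.array([-INF]),
        exchange_upper=[linear(kappa)],
    )
    env = EnvironmentSpec(metabolite_ids=["glucose"], initial_amounts=np.array([y0]))
    return model, env, np.array([x0])


def capped_growth(kappa: float = 1.0, cap: float = 10.0,
                  x0: float = 0.1, y0: float = 30.0
                  ) -> Tuple[MetabolicModel, EnvironmentSpec]:
    """monod_linear plus a hard growth cap g <= cap.

    While glucose is abundant the cap binds: growth is the constant `cap`
    and uptake 2*cap, independent of y.  With kappa=1, cap=10, x0=0.1,
    y0=30 the uptake bound becomes binding when y = 2*cap = 20, at
    t* = ln(51)/10, after which the dynamics reduce to the monod_linear
    segment and x -> x0 + y0/2 = 15.1.
    """
    model, env, x = monod_linear(kappa=kappa, x0=x0, y0=y0)
    model.id = "M"
    model.upper_flux = np.array([INF, float(cap)])
    model.validate()
    return model, env, x


def diauxie(capacity: float = 10.0, yield2: float = 0.5, kappa: float = 1.0,
            x0: float = 0.1, y0: Tuple[float, float] = (15.0, 15.0)
            ) -> Tuple[MetabolicModel, EnvironmentSpec]:
    """Two substrates, one shared transport capacity, unequal yields.

    Reactions (u1, u2, t, g): uptake of glucose and of a secondary substrate,
    a transporter pooling reaction t with u1 + u2 = t <= capacity, and growth
    g = u1 + yield2 * u2.  Glucose is preferred (higher yield): while
    kappa*y1 > capacity the optimum is u1 = capacity, u2 = 0 and growth is
    intrinsic; once glucose becomes rate-limiting the basis rewires and the
    spare capacity flows to substrate 2, creating a positive
    glucose -> substrate2 mediated effect.
    """
    model = MetabolicModel(
        id="D",
        reaction_ids=["u1", "u2", "t", "g"],
        internal_metabolite_ids=["transport_c", "carbon_c"],
        exchange_metabolite_ids=["glucose", "substrate2"],
        internal_stoich=np.array([
            [1.0, 1.0, -1.0, 0.0],
            [1.0, yield2, 0.0, -1.0],
        ]),
        exchange_stoich=np.array([
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
        ]),
        objective=np.array([0.0, 0.0, 0.0, 1.0]),
        lower_flux=np.array([0.0, 0.0, 0.0, 0.0]),
        upper_flux=np.array([INF, INF, float(capacity), INF]),
        exchange_lower=np.array([-INF, -INF]),
        exchange_upper=[linear(kappa), linear(kappa)],
    )
    env = EnvironmentSpec(
        metabolite_ids=["glucose", "substrate2"],
        initial_amounts=np.array(list(y0)),
    )
    return model, env, np.array([x0])


def crossfeed_pair(kappa: float = 1.0, x0: Tuple[float, float] = (0.1, 0.1),
                   glucose0: float = 10.0
                   ) -> Tuple[List[MetabolicModel], EnvironmentSpec, np.ndarray]:
    """Producer A secretes acetate; B grows on acetate alone.

    A: uptake uA, growth gA, secretion sA with balances uA - 2 gA = 0 and
    sA - gA = 0, so every unit of growth exports one unit of acetate.
    B: monod-type growth on acetate.  The expected species-species heuristic
    edge A -> B is positive (cross-feeding).
    """
    a = MetabolicModel(
        id="A",
        reaction_ids=["uA", "gA", "sA"],
        internal_metabolite_ids=["carbon_c", "byprod_c"],
        exchange_metabolite_ids=["glucose", "acetate"],
        internal_stoich=np.array([
            [1.0, -2.0, 0.0],
            [0.0, 1.0, -1.0],
        ]),
        exchange_stoich=np.array([
            [1.0, 0.0, 0.0],
            [0.0, 0.0, -1.0],  # secretion: negative uptake of acetate
        ]),
        objective=np.array([0.0, 1.0, 0.0]),
        lower_flux=np.array([0.0, 0.0, 0.0]),
        upper_flux=np.array([INF, 1000.0, INF]),
        exchange_lower=np.array([-INF, -INF]),
        exchange_upper=[linear(kappa), None],
    )
    b = MetabolicModel(
        id="B",
        reaction_ids=["uB", "gB"],
        internal_metabolite_ids=["carbon_c"],
        exchange_metabolite_ids=["acetate"],
        internal_stoich=np.array([[1.0, -2.0]]),
        exchange_stoich=np.array([[1.0, 0.0]]),
        objective=np.array([0.0, 1.0]),
        lower_flux=np.array([0.0, 0.0]),
        upper_flux=np.array([INF, 1000.0]),
        exchange_lower=np.array([-INF]),
        exchange_upper=[linear(kappa)],
    )
    env = EnvironmentSpec(
        metabolite_ids=["glucose", "acetate"],
        initial_amounts=np.array([glucose0, 0.0]),
    )
    return [a, b], env, np.array(list(x0))


def competition_pair(kappa: float = 1.0, x0: Tuple[float, float] = (0.1, 0.1),
                     glucose0: float = 10.0
                     ) -> Tuple[List[MetabolicModel], EnvironmentSpec, np.ndarray]:
    """Two identical monod-type microbes competing for one substrate.

    Both consume the single rate-limiting glucose pool, so the heuristic
    species-species weights are negative in both directions and symmetric.
    """
    m1, env, _ = monod_linear(kappa=kappa, y0=glucose0)
    m2, _, _ = monod_linear(kappa=kappa, y0=glucose0)
    m1.id, m2.id = "P", "Q"
    return [m1, m2], env, np.array(list(x0))


def futile_cycle(kappa: float = 1.0, cycle_cap: float = 5.0
                 ) -> Tuple[MetabolicModel, EnvironmentSpec, np.ndarray]:
    """monod_linear plus an internal 2-reaction cycle bounded by cycle_cap.

    The cycle (f1, f2 with f1 - f2 = 0 through a looped metabolite) carries
    no objective and exchanges nothing: any cycle flux adds to total flux
    without changing growth, so parsimonious refinement must zero it.
    """
    model = MetabolicModel(
        id="F",
        reaction_ids=["u", "g", "f1", "f2"],
        internal_metabolite_ids=["carbon_c", "loop_c"],
        internal_stoich=np.array([
            [1.0, -2.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, -1.0],
        ]),
        exchange_metabolite_ids=["glucose"],
        exchange_stoich=np.array([[1.0, 0.0, 0.0, 0.0]]),
        objective=np.array([0.0, 1.0, 0.0, 0.0]),
        lower_flux=np.array([0.0, 0.0, 0.0, 0.0]),
        upper_flux=np.array([INF, 1000.0, float(cycle_cap), float(cycle_cap)]),
        exchange_lower=np.array([-INF]),
        exchange_upper=[linear(kappa)],
    )
    env = EnvironmentSpec(metabolite_ids=["glucose"], initial_amounts=np.array([10.0]))
    return model, env, np.array([0.1])


def random_community(seed: int, max_microbes: int = 3, max_metabolites: int = 3
                     ) -> Tuple[List[MetabolicModel], EnvironmentSpec, np.ndarray]:
    """Seeded random small community for property tests (never for acceptance).

    Each microbe consumes a random nonempty subset of the metabolite pool
    through linear-bounded uptakes feeding one growth reaction with random
    yields, optionally secreting a byproduct proportional to growth.  The
    construction guarantees a bounded LP and non-negative dynamics.
    """
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, max_metabolites + 1))
    p = int(rng.integers(1, max_microbes + 1))
    met_ids = [f"met{j}" for j in range(m)]
    models: List[MetabolicModel] = []
    for i in range(p):
        k = int(rng.integers(1, m + 1))
        consumed = sorted(rng.choice(m, size=k, replace=False).tolist())
        secrete = bool(rng.random() < 0.4) and m > 1
        target = None
        if secrete:
            choices = [j for j in range(m) if j not in consumed]
            if choices:
                target = int(rng.choice(choices))
            else:
                secrete = False
        rids = [f"u{j}" for j in consumed] + ["g"] + (["s"] if secrete else [])
        n = len(rids)
        yields = rng.uniform(0.2, 1.0, size=k)
        sigma = float(rng.uniform(0.1, 0.8)) if secrete else 0.0
        # carbon balance: sum yields*u - g = 0 ; byproduct: sigma*g - s = 0
        internal = [list(yields) + [-1.0] + ([0.0] if secrete else [])]
        imets = ["carbon_c"]
        if secrete:
            internal.append([0.0] * k + [sigma, -1.0])
            imets.append("byprod_c")
        ex_ids = [met_ids[j] for j in consumed]
        ex = np.zeros((len(consumed) + (1 if secrete else 0), n))
        for col, _ in enumerate(consumed):
            ex[col, col] = 1.0
        if secrete:
            ex_ids.append(met_ids[target])
            ex[-1, n - 1] = -1.0
        kappas = rng.uniform(0.3, 2.0, size=k)
        ups = [linear(float(kp)) for kp in kappas] + ([None] if secrete else [])
        models.append(MetabolicModel(
            id=f"R{i}",
            reaction_ids=rids,
            internal_metabolite_ids=imets,
            exchange_metabolite_ids=ex_ids,
            internal_stoich=np.array(internal),
            exchange_stoich=ex,
            objective=np.array([0.0] * k + [1.0] + ([0.0] if secrete else [])),
            lower_flux=np.zeros(n),
            upper_flux=np.array([INF] * k + [1000.0] + ([INF] if secrete else [])),
            exchange_lower=np.full(len(ex_ids), -INF),
            exchange_upper=ups,
        ))
    env = EnvironmentSpec(
        metabolite_ids=met_ids,
        initial_amounts=rng.uniform(1.0, 10.0, size=m),
    )
    x0 = rng.uniform(0.05, 0.5, size=p)
    return models, env, x0
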