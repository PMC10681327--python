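"""Core data structures: metabolic models, environments, community state.

A :class:`MetabolicModel` holds the flux-balance problem data for one
organism, with the stoichiometry split into an internal-balance block
(internal metabolites x reactions, constrained to steady state) and an
exchange block (environmental metabolites x reactions).  The exchange block
is oriented so that a positive exchange rate means uptake — removal of the
metabolite from the shared environment; the sign flip into the environment
dynamics happens in the ODE right-hand side, never in the stored matrix.

Units are a labelling convention only: biomass in gDW, metabolites in mmol,
time in hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .bounds import BoundFunction, linear

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicModel",
    "EnvironmentSpec",
    "CommunityState",
    "align_environment",
    "ModelValidationError",
]

#: default uptake kinetics when a model supplies none: linear, kappa = 1 /h/gDW
DEFAULT_KAPPA = 1.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class MetabolicModel:
    """Flux-balance problem data for a single organism.

    Attributes
    ----------
    id:
        Organism label, used as the microbe node id in networks.
    reaction_ids:
        Ordered reaction labels; all vectors/matrices are in this order.
    internal_metabolite_ids:
        Row labels of ``internal_stoich``.
    exchange_metabolite_ids:
        Row labels of ``exchange_stoich`` (environment metabolite ids).
    internal_stoich:
        Internal-balance stoichiometry; rows are constrained to
        ``internal_stoich @ psi = 0``.
    exchange_stoich:
        Exchange stoichiometry; ``exchange_stoich @ psi`` is the vector of
        uptake rates (positive = removal from the environment).
    objective:
        Growth objective coefficients over reactions.
    lower_flux, upper_flux:
        Constant flux bounds (may be +-inf).
    exchange_lower:
        Constant lower bounds on each exchange row (may be -inf; 0 forbids
        secretion through that row).
    exchange_upper:
        Per exchange row, a :class:`BoundFunction` of the corresponding
        environment metabolite, or ``None`` for the default linear kinetics.
    """

    id: str
    reaction_ids: List[str]
    internal_metabolite_ids: List[str]
    exchange_metabolite_ids: List[str]
    internal_stoich: np.ndarray
    exchange_stoich: np.ndarray
    objective: np.ndarray
    lower_flux: np.ndarray
    upper_flux: np.ndarray
    exchange_lower: np.ndarray
    exchange_upper: List[Optional[BoundFunction]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.internal_stoich = np.atleast_2d(np.asarray(self.internal_stoich, dtype=float))
        self.exchange_stoich = np.atleast_2d(np.asarray(self.exchange_stoich, dtype=float))
        if self.internal_stoich.size == 0:
            self.internal_stoich = self.internal_stoich.reshape(0, self.n_reactions)
        if self.exchange_stoich.size == 0:
            self.exchange_stoich = self.exchange_stoich.reshape(0, self.n_reactions)
        self.objective = np.asarray(self.objective, dtype=float)
        self.lower_flux = np.asarray(self.lower_flux, dtype=float)
        self.upper_flux = np.asarray(self.upper_flux, dtype=float)
        self.exchange_lower = np.asarray(self.exchange_lower, dtype=float)
        if not self.exchange_upper:
            self.exchange_upper = [None] * len(self.exchange_metabolite_ids)
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        n = self.n_reactions
        if self.internal_stoich.shape != (len(self.internal_metabolite_ids), n):
            raise ModelValidationError(
                f"{self.id}: internal_stoich shape {self.internal_stoich.shape} "
                f"!= ({len(self.internal_metabolite_ids)}, {n})"
            )
        if self.exchange_stoich.shape != (len(self.exchange_metabolite_ids), n):
            raise ModelValidationError(
                f"{self.id}: exchange_stoich shape {self.exchange_stoich.shape} "
                f"!= ({len(self.exchange_metabolite_ids)}, {n})"
            )
        for name, vec in (("objective", self.objective), ("lower_flux", self.lower_flux),
                          ("upper_flux", self.upper_flux)):
            if vec.shape != (n,):
                raise ModelValidationError(f"{self.id}: {name} length != n_reactions")
        if np.any(self.lower_flux > self.upper_flux):
            raise ModelValidationError(f"{self.id}: lower_flux > upper_flux somewhere")
        if not np.any(self.objective != 0):
            raise ModelValidationError(f"{self.id}: no objective (all-zero objective vector)")
        m = len(self.exchange_metabolite_ids)
        if len(set(self.exchange_metabolite_ids)) != m:
            raise ModelValidationError(f"{self.id}: duplicate exchange metabolite ids")
        if self.exchange_lower.shape != (m,):
            raise ModelValidationError(f"{self.id}: exchange_lower length != n exchange rows")
        if len(self.exchange_upper) != m:
            raise ModelValidationError(f"{self.id}: exchange_upper length != n exchange rows")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def exchange_bound(self, j: int) -> BoundFunction:
        """The uptake bound function for exchange row ``j`` (default linear)."""
        fn = self.exchange_upper[j]
        return fn if fn is not None else linear(DEFAULT_KAPPA)

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            reaction_ids=list(self.reaction_ids),
            internal_metabolite_ids=list(self.internal_metabolite_ids),
            exchange_metabolite_ids=list(self.exchange_metabolite_ids),
            internal_stoich=self.internal_stoich.copy(),
            exchange_stoich=self.exchange_stoich.copy(),
            objective=self.objective.copy(),
            lower_flux=self.lower_flux.copy(),
            upper_flux=self.upper_flux.copy(),
            exchange_lower=self.exchange_lower.copy(),
            exchange_upper=list(self.exchange_upper),
        )


@dataclass
class EnvironmentSpec:
    """The shared metabolite pool: ids, initial amounts, constant inflow."""

    metabolite_ids: List[str]
    initial_amounts: np.ndarray
    inflow: Optional[np.ndarray] = None
    significance_threshold: float = 0.01

    def __post_init__(self) -> None:
        self.initial_amounts = np.asarray(self.initial_amounts, dtype=float)
        if self.inflow is None:
            self.inflow = np.zeros(len(self.metabolite_ids))
        self.inflow = np.asarray(self.inflow, dtype=float)
        if self.initial_amounts.shape != (len(self.metabolite_ids),):
            raise ModelValidationError("initial_amounts length != metabolite_ids")
        if self.inflow.shape != (len(self.metabolite_ids),):
            raise ModelValidationError("inflow length != metabolite_ids")
        if np.any(self.initial_amounts < 0):
            raise ModelValidationError("initial_amounts must be >= 0")
        if not np.all(np.isfinite(self.inflow)):
            raise ModelValidationError("inflow must be finite")

    def index(self, metabolite_id: str) -> int:
        return self.metabolite_ids.index(metabolite_id)

    def copy(self) -> "EnvironmentSpec":
        return EnvironmentSpec(
            metabolite_ids=list(self.metabolite_ids),
            initial_amounts=self.initial_amounts.copy(),
            inflow=self.inflow.copy(),
            significance_threshold=self.significance_threshold,
        )


@dataclass
class CommunityState:
    """Community snapshot: time (h), biomass x (gDW), metabolites y (mmol)."""

    time: float
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)


def align_environment(
    models: Sequence[MetabolicModel],
    env: EnvironmentSpec,
    strict: bool = False,
) -> tuple:
    """Reindex every model's exchange block to the environment's metabolite order.

    Community coupling requires all organisms to address one shared metabolite
    pool, so all exchange matrices are rewritten with identical row ordering
    equal to ``env.metabolite_ids``; rows for metabolites a model does not
    touch are zero.  With ``strict=False`` (default) metabolites present in a
    model but absent from the environment are appended to the environment
    with initial amount 0; with ``strict=True`` that is an error.

    Returns ``(aligned_models, aligned_env)``.  Idempotent.
    """
    env = env.copy()
    for model in models:
        for met in model.exchange_metabolite_ids:
            if met not in env.metabolite_ids:
                if strict:
                    raise ModelValidationError(
                        f"model {model.id}: exchange metabolite {met!r} not in environment"
                    )
                env.metabolite_ids.append(met)
                env.initial_amounts = np.append(env.initial_amounts, 0.0)
                env.inflow = np.append(env.inflow, 0.0)
                logger.warning("environment grown by metabolite %r (y0=0)", met)

    m = len(env.metabolite_ids)
    aligned: List[MetabolicModel] = []
    for model in models:
        ex = np.zeros((m, model.n_reactions))
        lo = np.full(m, -np.inf)
        ups: List[Optional[BoundFunction]] = [None] * m
        for j, met in enumerate(model.exchange_metabolite_ids):
            k = env.metabolite_ids.index(met)
            ex[k, :] = model.exchange_stoich[j, :]
            lo[k] = model.exchange_lower[j]
            ups[k] = model.exchange_upper[j]
        new = model.copy()
        new.exchange_metabolite_ids = list(env.metabolite_ids)
        new.exchange_stoich = ex
        new.exchange_lower = lo
        new.exchange_upper = ups
        aligned.append(new)
    return aligned, env
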