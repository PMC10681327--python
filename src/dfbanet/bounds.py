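"""Metabolite-dependent uptake-bound functions.

Uptake of an environmental metabolite is limited by its availability: the
upper bound on the transport flux is a non-decreasing function c2(y) of the
metabolite amount y.  Three kinds are supported: a constant, a linear law
kappa * y (mass-action-like transport), and a Michaelis-Menten saturating law
Vmax * y / (K + y).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

__all__ = ["BoundFunction", "constant", "linear", "michaelis_menten"]

_KINDS = ("constant", "linear", "michaelis_menten")


@dataclass(frozen=True)
class BoundFunction:
    """A non-decreasing bound c2(y) on an uptake flux.

    Parameters
    ----------
    kind:
        One of ``"constant"``, ``"linear"``, ``"michaelis_menten"``.
    params:
        ``(value,)`` for constant, ``(kappa,)`` for linear,
        ``(vmax, km)`` for Michaelis-Menten.
    """

    kind: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown bound kind {self.kind!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if self.kind == "constant":
            if len(p) != 1:
                raise ValueError("constant bound takes one parameter")
            if p[0] < 0:
                raise ValueError("constant bound must be >= 0")
        elif self.kind == "linear":
            if len(p) != 1:
                raise ValueError("linear bound takes one parameter (kappa)")
            if p[0] < 0:
                raise ValueError("linear slope kappa must be >= 0")
        else:
            if len(p) != 2:
                raise ValueError("michaelis_menten takes (vmax, km)")
            if p[0] < 0 or p[1] <= 0:
                raise ValueError("require vmax >= 0 and km > 0")

    def __call__(self, y: float) -> float:
        y = max(float(y), 0.0)  # bounds are only meaningful for y >= 0
        if self.kind == "constant":
            return self.params[0]
        if self.kind == "linear":
            return self.params[0] * y
        vmax, km = self.params
        return vmax * y / (km + y)

    def derivative(self, y: float) -> float:
        """d c2 / dy, used for first-order slack-derivative checks."""
        y = max(float(y), 0.0)
        if self.kind == "constant":
            return 0.0
        if self.kind == "linear":
            return self.params[0]
        vmax, km = self.params
        return vmax * km / (km + y) ** 2

    @property
    def is_constant(self) -> bool:
        return self.kind == "constant"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundFunction":
        return cls(kind=d["kind"], params=tuple(d["params"]))


def constant(value: float) -> BoundFunction:
    return BoundFunction("constant", (value,))


def linear(kappa: float) -> BoundFunction:
    return BoundFunction("linear", (kappa,))


def michaelis_menten(vmax: float, km: float) -> BoundFunction:
    return BoundFunction("michaelis_menten", (vmax, km))
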