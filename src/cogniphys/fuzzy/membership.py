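"""Fuzzy-set membership functions: trapezoid, Gaussian, sigmoid.

Each family validates its parameters at construction (never at
evaluation), evaluates vectorised on numpy arrays with outputs in [0, 1],
and exposes its analytic derivative for first-order uncertainty
propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MembershipFunction", "Trapezoid", "Gaussian", "Sigmoid", "membership_from_dict"]


class MembershipFunction:
    """Base class; subclasses implement __call__ and derivative."""

    family: str

    def __call__(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def derivative(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Trapezoid(MembershipFunction):
    """Piecewise-linear trapezoid: 0 outside [a, d], 1 on [b, c]."""

    a: float
    b: float
    c: float
    d: float
    family = "trapezoid"

    def __post_init__(self) -> None:
        if not (self.a < self.b <= self.c < self.d):
            raise ValueError(
                f"trapezoid requires a < b <= c < d, got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        up = (x - self.a) / (self.b - self.a)
        down = (self.d - x) / (self.d - self.c)
        out = np.minimum(np.minimum(up, down), 1.0)
        return np.maximum(out, 0.0)

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        out[(x > self.a) & (x < self.b)] = 1.0 / (self.b - self.a)
        out[(x > self.c) & (x < self.d)] = -1.0 / (self.d - self.c)
        return out

    def to_dict(self) -> dict:
        return {"family": "trapezoid", "params": [self.a, self.b, self.c, self.d]}


@dataclass(frozen=True)
class Gaussian(MembershipFunction):
    """exp(-(x - c)^2 / (2 sigma^2)); peak value 1 at x = c."""

    c: float
    sigma: float
    family = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"gaussian requires sigma > 0, got {self.sigma}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return np.exp(-((x - self.c) ** 2) / (2.0 * self.sigma**2))

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        return -(x - self.c) / self.sigma**2 * self(x)

    def to_dict(self) -> dict:
        return {"family": "gaussian", "params": [self.c, self.sigma]}


@dataclass(frozen=True)
class Sigmoid(MembershipFunction):
    """1 / (1 + exp(-a (x - c))); value 0.5 at the inflection x = c."""

    a: float
    c: float
    family = "sigmoid"

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("sigmoid requires a != 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        # clipped exponent for numerical safety far in the tail
        z = np.clip(-self.a * (x - self.c), -700, 700)
        return 1.0 / (1.0 + np.exp(z))

    def derivative(self, x):
        mu = self(x)
        return self.a * mu * (1.0 - mu)

    def to_dict(self) -> dict:
        return {"family": "sigmoid", "params": [self.a, self.c]}


_FAMILIES = {"trapezoid": Trapezoid, "gaussian": Gaussian, "sigmoid": Sigmoid}


def membership_from_dict(d: dict) -> MembershipFunction:
    """Build a membership function from {"family": ..., "params": [...]}."""
    try:
        cls = _FAMILIES[d["family"]]
    except KeyError:
        raise ValueError(f"unknown membership family {d.get('family')!r}") from None
    return cls(*d["params"])
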