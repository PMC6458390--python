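"""Geometric and kinetic forward models for secondary-xylem growth.

Early secondary xylem in the Arabidopsis root occupies an inverted cone:
its base is the secondary-xylem cross-section area ``a`` at the root base
(the uppermost position) and its height is the longitudinal extension
``h`` of secondary growth along the root. Each measured quantity — base
area, cell number, extension and reconstructed cone volume — expands
exponentially over the early developmental window, X(t) = X0 * exp(k*t),
which is the solution of the simplified (linear) Lockhart growth law
dX/dt = k*X. The radial and longitudinal growth modes are coupled by an
allometric power law h = c * a**p.

All lengths are mm, areas mm^2, volumes mm^3 and times days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExponentialParams",
    "AllometricParams",
    "ConeGeometry",
    "cone_volume",
    "forward_exponential",
    "height_from_area",
    "allometric_height",
]


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters (X0, k) of an exponential trajectory X(t) = X0 * e**(k t).

    X0 carries the units of the modelled quantity (mm^2, mm^3, mm or
    cells); k is the growth constant in 1/day. Any quantity carries its
    own k; the functional form is the same for all of them.
    """

    X0: float
    k: float

    def __post_init__(self):
        if not (self.X0 > 0 and math.isfinite(self.X0)):
            raise ValueError(f"X0 must be finite and > 0, got {self.X0}")
        if not math.isfinite(self.k):
            raise ValueError(f"k must be finite, got {self.k}")


@dataclass(frozen=True)
class AllometricParams:
    """Parameters (c, p) of the allometric relation h = c * a**p.

    p is the dimensionless scaling exponent; c carries the compensating
    units (mm * mm^(-2p) when a is in mm^2).
    """

    c: float
    p: float

    def __post_init__(self):
        if not (self.c > 0 and math.isfinite(self.c)):
            raise ValueError(f"c must be finite and > 0, got {self.c}")
        if not math.isfinite(self.p):
            raise ValueError(f"p must be finite, got {self.p}")


@dataclass(frozen=True)
class ConeGeometry:
    """A cone described by its base area and height.

    The radius is always derived as r = sqrt(a/pi) so the a = pi*r**2
    constraint cannot be violated; the volume is a*h/3.
    """

    a: float
    h: float

    def __post_init__(self):
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")

    @property
    def r(self) -> float:
        return math.sqrt(self.a / math.pi)

    @property
    def V(self) -> float:
        return cone_volume(self.a, self.h)


def cone_volume(a, h):
    """Volume of a cone with base area ``a`` (mm^2) and height ``h`` (mm).

    Identically (1/3)*pi*r**2*h with a = pi*r**2; bilinear in (a, h).
    Accepts scalars or arrays; negative inputs are rejected.
    """
    a = np.asarray(a, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(a < 0):
        raise ValueError("base area a must be >= 0")
    if np.any(h < 0):
        raise ValueError("height h must be >= 0")
    out = a * h / 3.0
    return float(out) if out.ndim == 0 else out


def forward_exponential(params: ExponentialParams, t):
    """Evaluate X(t) = X0 * exp(k * t) at time(s) ``t`` in days."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    out = params.X0 * np.exp(params.k * t)
    return float(out) if out.ndim == 0 else out


def height_from_area(params: ExponentialParams, a, t):
    """Longitudinal extension implied by the cone model at time ``t``.

    Given the fitted exponential volume trajectory V(t) = V0*e**(k t) and
    a base area ``a`` (mm^2), the cone geometry V = a*h/3 inverts to
    h = 3*V0*e**(k t) / a (equivalently 3*V0*e**(k t) / (pi*r**2)).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ZeroDivisionError("base area a must be > 0 to infer height")
    out = 3.0 * forward_exponential(params, t) / a
    return float(out) if np.ndim(out) == 0 else out


def allometric_height(params: AllometricParams, a):
    """Evaluate the allometric relation h = c * a**p for base area ``a``."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("base area a must be > 0")
    out = params.c * a ** params.p
    return float(out) if out.ndim == 0 else out
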