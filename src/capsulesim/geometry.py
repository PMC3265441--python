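"""Axisymmetric capsule exterior geometry.

The capsule is a solid of revolution about the axial coordinate ``x``.
Its radius profile rises exponentially from a tip radius ``r`` toward a
maximum radius ``R`` (approached asymptotically, never reached) with
slope constant ``alpha``, and is mirror symmetric about the midpoint of
the capsule length ``L``::

    f(x) = (R - r) * (1 - exp(-alpha * x)) + r,        0   <= x < L/2
    f(x) = (R - r) * (1 - exp( alpha * (x - L))) + r,  L/2 <= x <= L

Large ``alpha`` gives a nearly cylindrical pill with blunt shoulders;
small ``alpha`` gives a streamlined, slowly tapering body.  All force
computations in :mod:`capsulesim.forces` reduce to surface integrals of
a pressure field over this profile, so the quadrature helpers live here.

All quantities are SI (metres).  The profile equation is scale
covariant, so the same formulas hold verbatim in millimetres; the
:meth:`CapsuleShape.from_mm` constructor converts configuration-facing
millimetre values at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

__all__ = ["CapsuleShape", "surface_integral", "MM"]

#: metres per millimetre (conversion factor used at configuration boundaries)
MM = 1e-3

#: default number of quadrature nodes for composite Simpson integration
DEFAULT_QUAD_POINTS = 501


@dataclass(frozen=True)
class CapsuleShape:
    """Parametric axisymmetric capsule exterior.

    Parameters
    ----------
    r : float
        Initial (tip) radius at both ends, metres.  ``0 < r <= R``.
    R : float
        Maximum radius (supremum of the profile), metres.
    alpha : float
        Slope constant, 1/metre.  Controls how fast the profile rises
        from ``r`` toward ``R``.
    L : float
        Capsule length, metres.
    """

    r: float
    R: float
    alpha: float
    L: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r <= self.R):
            raise ValueError(f"require 0 < r <= R, got r={self.r}, R={self.R}")
        if not self.alpha > 0.0:
            raise ValueError(f"require alpha > 0, got alpha={self.alpha}")
        if not self.L > 0.0:
            raise ValueError(f"require L > 0, got L={self.L}")

    @classmethod
    def from_mm(cls, r_mm: float, R_mm: float, alpha_per_mm: float,
                L_mm: float) -> "CapsuleShape":
        """Build a shape from millimetre-based configuration values."""
        return cls(r=r_mm * MM, R=R_mm * MM, alpha=alpha_per_mm / MM,
                   L=L_mm * MM)

    # -- profile and derivatives -------------------------------------

    def _check_domain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0.0) or np.any(x > self.L):
            raise ValueError(
                f"axial position outside capsule domain [0, {self.L}]")
        return x

    def profile(self, x) -> np.ndarray:
        """Radius ``f(x)`` of the exterior surface at axial position x (m).

        Continuous everywhere, mirror symmetric about ``L/2``.
        """
        x = self._check_domain(x)
        dR = self.R - self.r
        rear = dR * (1.0 - np.exp(-self.alpha * x)) + self.r
        front = dR * (1.0 - np.exp(self.alpha * (x - self.L))) + self.r
        return np.where(x < 0.5 * self.L, rear, front)

    def dprofile(self, x) -> np.ndarray:
        """One-sided derivative ``f'(x)``, by side of the midpoint.

        The profile is C0 but not C1 at ``x = L/2``; there the average
        of the two one-sided slopes (which is exactly zero, since the
        slopes are equal and opposite) is returned, so all integrands
        are defined on the full closed interval.
        """
        x = self._check_domain(x)
        dR = self.R - self.r
        rear = dR * self.alpha * np.exp(-self.alpha * x)
        front = -dR * self.alpha * np.exp(self.alpha * (x - self.L))
        out = np.where(x < 0.5 * self.L, rear, front)
        return np.where(x == 0.5 * self.L, 0.0, out)

    def slope_angle(self, x) -> np.ndarray:
        """Surface slope angle ``theta(x) = pi/2 - arctan(f'(x))`` in rad.

        ``theta`` lies in (0, pi): below pi/2 on the rising rear ramp,
        exactly pi/2 where the surface is locally cylindrical, above
        pi/2 on the falling front ramp.
        """
        return 0.5 * np.pi - np.arctan(self.dprofile(x))

    # -- integral quantities -----------------------------------------

    def quadrature_grid(self, n: int = DEFAULT_QUAD_POINTS) -> np.ndarray:
        """Uniform axial grid on [0, L] with an odd number of nodes."""
        if n < 3:
            raise ValueError("need at least 3 quadrature nodes")
        if n % 2 == 0:
            n += 1  # composite Simpson needs an odd node count
        return np.linspace(0.0, self.L, n)

    def internal_volume(self, n: int = DEFAULT_QUAD_POINTS) -> float:
        """Volume of the solid of revolution, ``pi * int f(x)^2 dx`` (m^3)."""
        x = self.quadrature_grid(n)
        f = self.profile(x)
        return float(np.pi * simpson(f * f, x=x))

    def export_profile(self, n: int = 201) -> np.ndarray:
        """Two-column array ``(x_mm, radius_mm)`` for plotting/export."""
        x = np.linspace(0.0, self.L, n)
        return np.column_stack([x / MM, self.profile(x) / MM])


def surface_integral(shape: CapsuleShape, pressure, n: int = DEFAULT_QUAD_POINTS) -> float:
    """Integrate a pressure field over the capsule's lateral surface.

    Computes ``2*pi * int_0^L p(x) f(x) sqrt(1 + f'(x)^2) dx`` by
    composite Simpson quadrature on a uniform grid — the total normal
    load on the surface of revolution for a pressure ``p`` acting
    normal to it.

    Parameters
    ----------
    shape : CapsuleShape
    pressure : callable or array_like
        Either a function of axial position (m) returning pressure (Pa),
        or an array of pressures already sampled on ``shape.quadrature_grid(n)``.
    n : int
        Number of quadrature nodes.

    Returns
    -------
    float
        Force in newtons.
    """
    x = shape.quadrature_grid(n)
    p = pressure(x) if callable(pressure) else np.asarray(pressure, dtype=float)
    if p.shape != x.shape:
        raise ValueError("pressure array must match the quadrature grid")
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("non-finite pressure values in surface integral")
    f = shape.profile(x)
    df = shape.dprofile(x)
    integrand = p * f * np.sqrt(1.0 + df * df)
    return float(2.0 * np.pi * simpson(integrand, x=x))
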