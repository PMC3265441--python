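"""Force balance on the capsule: moving force, friction, drag.

The tissue presses on the capsule surface with the total pressure
``Ps + Pi`` (stimulated contraction plus passive distension).  Only the
component normal to the sloped surface acts on the capsule,

    P1 = (Ps + Pi) * sin(theta(x)),   theta = pi/2 - arctan(f'(x)),

and decomposes into an axial (propulsive) part on the ramps and a
radial part that loads the Coulomb friction:

    F_m = 2*pi * int P1 cos(theta) f sqrt(1 + f'^2) dx     (signed)
    F_f = 2*pi * mu * int P1 sin(theta) f sqrt(1 + f'^2) dx  (magnitude)

With ``theta`` taken from the signed slope, cos(theta) is positive on
the rising rear ramp and negative on the falling front ramp, so a
pressure field that is mirror symmetric about the capsule midpoint
produces zero net moving force and only the fore-aft asymmetry of the
contraction propels the capsule.  In the cylinder limit (f' = 0) the
moving force vanishes for any pressure: the exterior shape alone
determines whether the capsule can move.

Drag is Stokes-like, ``F_d = b * v`` (the capsule creeps at mm/s).  The
drag coefficient ``b`` is either a user constant or a thin-film annular
lubrication surrogate.  All quantities SI (Pa, m, N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .geometry import DEFAULT_QUAD_POINTS, CapsuleShape

__all__ = ["ForceBreakdown", "DragModel", "pressure_normal",
           "moving_force", "friction_force", "drag_force", "net_force"]


@dataclass(frozen=True)
class ForceBreakdown:
    """Instantaneous force decomposition (N): F_t = F_m - F_f - F_d exactly."""

    F_m: float  # axial moving force, signed (+ toward the front end)
    F_f: float  # friction, signed so that it opposes motion
    F_d: float  # drag, signed so that it opposes motion
    F_t: float  # net force

    def __post_init__(self) -> None:
        expected = self.F_m - self.F_f - self.F_d
        if self.F_t != expected:
            raise ValueError("force breakdown violates F_t = F_m - F_f - F_d")


def net_force(F_m: float, F_f: float, F_d: float) -> ForceBreakdown:
    """Combine the three components; the identity holds bit-exactly."""
    return ForceBreakdown(F_m=F_m, F_f=F_f, F_d=F_d,
                          F_t=F_m - F_f - F_d)


def pressure_normal(Ps, Pi, theta) -> np.ndarray:
    """Surface-normal pressure ``P1 = (Ps + Pi) sin(theta)``, clamped >= 0.

    The clamp encodes contact without adhesion: tissue can push on the
    capsule but never pull.
    """
    total = np.asarray(Ps, dtype=float) + np.asarray(Pi, dtype=float)
    return np.maximum(total * np.sin(np.asarray(theta, dtype=float)), 0.0)


def _fields(shape: CapsuleShape, P1, n):
    x = shape.quadrature_grid(n)
    p1 = P1(x) if callable(P1) else np.asarray(P1, dtype=float)
    if p1.shape != x.shape:
        raise ValueError("P1 field must match the quadrature grid")
    f = shape.profile(x)
    df = shape.dprofile(x)
    # algebraic forms of cos/sin(theta) with theta = pi/2 - arctan(f');
    # exact (no pi/2 rounding) where the surface is cylindrical
    root = np.sqrt(1.0 + df * df)
    cos_t = df / root
    sin_t = 1.0 / root
    area = f * root
    return x, p1, cos_t, sin_t, area


def moving_force(shape: CapsuleShape, P1, n: int = DEFAULT_QUAD_POINTS) -> float:
    """Signed axial force (N) from a normal-pressure field P1(x).

    Positive drives the capsule toward its front (x = L) end.  Pressure
    on the rear ramp pushes forward, on the front ramp backward, and a
    symmetric field cancels exactly.
    """
    x, p1, cos_t, _, area = _fields(shape, P1, n)
    return float(2.0 * np.pi * simpson(p1 * cos_t * area, x=x))


def friction_force(shape: CapsuleShape, P1, mu: float,
                   n: int = DEFAULT_QUAD_POINTS) -> float:
    """Kinetic-friction magnitude (N, >= 0) from a normal-pressure field.

    ``2*pi*mu * int P1 sin(theta) f sqrt(1+f'^2) dx``.  The caller
    applies the sign opposing motion (and the stiction clamp at rest).
    """
    if mu < 0:
        raise ValueError("friction coefficient must be nonnegative")
    x, p1, _, sin_t, area = _fields(shape, P1, n)
    return float(2.0 * np.pi * mu * simpson(p1 * sin_t * area, x=x))


def drag_force(b: float, v: float) -> float:
    """Stokes drag ``b * v`` (N), signed so that it opposes motion."""
    if b < 0:
        raise ValueError("drag coefficient must be nonnegative")
    return b * v


@dataclass(frozen=True)
class DragModel:
    """Velocity-proportional drag ``F_d = b v``.

    ``mode='constant'`` takes ``b`` (N s/m) directly from configuration.
    ``mode='surrogate'`` estimates ``b`` from a thin annular lubrication
    film between the capsule surface and the lumen wall: a Couette shear
    film of thickness ``t`` over each surface slice gives

        b = 2*pi*eta * int f(x) / (c - f(x)) dx,   c = R + t,

    which for a cylinder reduces to ``2*pi*eta*R*L/t``.  The surrogate
    is deliberately shape-insensitive at creeping speeds.
    """

    b: float
    mode: str = "constant"

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("drag coefficient must be nonnegative")

    @classmethod
    def constant(cls, b: float) -> "DragModel":
        return cls(b=b, mode="constant")

    @classmethod
    def surrogate(cls, shape: CapsuleShape, viscosity: float,
                  film_thickness: float,
                  n: int = DEFAULT_QUAD_POINTS) -> "DragModel":
        if viscosity <= 0 or film_thickness <= 0:
            raise ValueError("viscosity and film thickness must be positive")
        x = shape.quadrature_grid(n)
        f = shape.profile(x)
        c = shape.R + film_thickness
        b = 2.0 * np.pi * viscosity * simpson(f / (c - f), x=x)
        return cls(b=float(b), mode="surrogate")

    def force(self, v: float) -> float:
        return drag_force(self.b, v)
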