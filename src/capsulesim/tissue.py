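"""Passive small-intestine mechanics: strain, stress relaxation, wall pressure.

The intestine is treated as a thin-walled viscoelastic cylindrical
vessel that the capsule distends.  Circumferential strain follows from
the local capsule radius versus the resting lumen diameter; the wall
stress under that (held) strain relaxes as a two-exponential-plus-
constant spectrum; and the thin-wall relation ``P = 2*h*sigma/d`` turns
wall stress into the pressure the tissue exerts back on the capsule.

Units are SI internally (m, s, Pa).  The relaxation amplitudes are
interpreted as kPa per unit strain by default (stored in Pa), with a
single dimensionless ``stress_scale`` exposed because the source model
does not state units for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .geometry import MM, CapsuleShape

__all__ = ["TissueParams", "strain", "relaxation_stress", "wall_pressure"]

KPA = 1e3  # Pa per kPa

#: measured relaxation spectrum, kPa per unit strain: two decaying terms
#: and a long-time plateau.
DEFAULT_RELAX_AMPLITUDES_KPA = (0.7, 0.63, 0.92)
#: literal alternative spectrum printed alongside the thin-wall formula
#: in the source model (not a consistent rescaling of the measured one).
ALT_RELAX_AMPLITUDES_KPA = (7.0, 6.3, 5.0)
DEFAULT_RELAX_TAUS_S = (18.0, 1.6)


@dataclass(frozen=True)
class TissueParams:
    """Passive and active tissue constants.

    Parameters
    ----------
    d0 : float
        Resting (undistended) lumen diameter, m.
    h : float
        Wall thickness, m.
    mu : float
        Coulomb friction coefficient between capsule and mucosa
        (dimensionless, measured at 0.1).
    relax_amplitudes : tuple of 3 floats
        Relaxation spectrum amplitudes (Pa per unit strain): two
        decaying terms then the long-time plateau.
    relax_taus : tuple of 2 floats
        Time constants (s) of the two decaying terms.
    stress_scale : float
        Dimensionless multiplier on the whole spectrum (the source data
        do not state units; this exposes the modulus calibration).
    tau_s : float
        Rising time constant of the stimulated contraction (s),
        measured as 17.3 +- 8.3 s.
    strain_mode : str
        'diameter_ratio' (default): strain = max(0, 2 f(x)/d0 - 1),
        reading the distended local diameter as twice the capsule
        radius.  'literal': strain = max(0, f(x)/d0 - 1), the printed
        radius-over-diameter form, kept for traceability.
    relaxation_mode : str
        'measured' (default): measured spectrum amplitudes.  'alternative':
        the alternative printed amplitudes (7, 6.3, 5) kPa.
    """

    d0: float
    h: float
    mu: float = 0.1
    relax_amplitudes: Tuple[float, float, float] = tuple(
        a * KPA for a in DEFAULT_RELAX_AMPLITUDES_KPA)
    relax_taus: Tuple[float, float] = DEFAULT_RELAX_TAUS_S
    stress_scale: float = 1.0
    tau_s: float = 17.3
    strain_mode: str = "diameter_ratio"
    relaxation_mode: str = "measured"

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.h <= 0:
            raise ValueError("d0 and h must be positive")
        if not (0.0 <= self.mu < 1.0):
            raise ValueError(f"require 0 <= mu < 1, got {self.mu}")
        if len(self.relax_amplitudes) != 3 or any(
                a <= 0 for a in self.relax_amplitudes):
            raise ValueError("relaxation spectrum needs 3 positive amplitudes")
        if len(self.relax_taus) != 2 or any(t <= 0 for t in self.relax_taus):
            raise ValueError("relaxation spectrum needs 2 positive time constants")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.strain_mode not in ("diameter_ratio", "literal"):
            raise ValueError(f"unknown strain_mode {self.strain_mode!r}")
        if self.relaxation_mode not in ("measured", "alternative"):
            raise ValueError(f"unknown relaxation_mode {self.relaxation_mode!r}")

    @classmethod
    def from_mm(cls, d0_mm: float, h_mm: float, **kw) -> "TissueParams":
        if "relax_amplitudes_kpa" in kw:
            kw["relax_amplitudes"] = tuple(
                a * KPA for a in kw.pop("relax_amplitudes_kpa"))
        return cls(d0=d0_mm * MM, h=h_mm * MM, **kw)

    @property
    def amplitudes(self) -> np.ndarray:
        """Effective spectrum amplitudes (Pa) after mode and scale."""
        if self.relaxation_mode == "alternative":
            amps = np.array(ALT_RELAX_AMPLITUDES_KPA) * KPA
        else:
            amps = np.asarray(self.relax_amplitudes, dtype=float)
        return amps * self.stress_scale


def strain(shape: CapsuleShape, x, params: TissueParams) -> np.ndarray:
    """Circumferential strain of the lumen at axial position(s) x (m).

    Zero wherever the capsule does not distend the resting lumen
    (strain is clipped at zero: the wall cannot be in circumferential
    compression against the capsule).
    """
    f = shape.profile(x)
    if params.strain_mode == "literal":
        eps = f / params.d0 - 1.0
    else:
        eps = 2.0 * f / params.d0 - 1.0
    return np.maximum(eps, 0.0)


def relaxation_stress(strain_value, t_since_stretch, params: TissueParams) -> np.ndarray:
    """Viscoelastic wall stress (Pa) at time t after a step stretch.

    ``sigma(t) = eps * (A1 exp(-t/tau1) + A2 exp(-t/tau2) + A_inf)``;
    strictly decreasing in t for positive strain, with long-time limit
    ``A_inf * eps``.
    """
    eps = np.asarray(strain_value, dtype=float)
    t = np.asarray(t_since_stretch, dtype=float)
    if np.any(eps < 0):
        raise ValueError("strain must be nonnegative")
    if np.any(t < 0):
        raise ValueError("time since stretch must be nonnegative")
    a1, a2, ainf = params.amplitudes
    t1, t2 = params.relax_taus
    return eps * (a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + ainf)


def wall_pressure(shape: CapsuleShape, x, t_since_stretch,
                  params: TissueParams) -> np.ndarray:
    """Passive internal pressure (Pa) on the capsule from the distended wall.

    Thin-wall relation ``Pi = (2 h / d) * sigma`` applied pointwise with
    the local distended diameter ``d(x) = 2 f(x)``.  Identically zero
    wherever the strain is zero.
    """
    eps = strain(shape, x, params)
    d = 2.0 * shape.profile(x)
    sigma = relaxation_stress(eps, t_since_stretch, params)
    return np.where(eps > 0.0, (2.0 * params.h / d) * sigma, 0.0)
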