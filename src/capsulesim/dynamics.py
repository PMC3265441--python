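"""Forward simulation of capsule locomotion.

The simulation advances two coupled pieces of state with a fixed-step
explicit Euler loop (default step 1 ms, small against every time
constant in the model):

* a lab-frame tissue field on a uniform axial grid — the stimulated
  contraction pressure ``Ps`` at each node relaxes first-order toward
  its moving target ``Pm * G(x - x0(t))`` (the dose-response plateau
  weighted by the Gaussian electrode footprint, which travels with the
  capsule) with rising time constant ``tau_s``, and decays the same way
  once the footprint moves on; each node also carries a stretch clock
  recording when the capsule first strained it, which drives the
  viscoelastic relaxation of the passive wall pressure ``Pi``;

* the capsule rigid body — at every step the normal pressure
  ``P1 = (Ps + Pi) sin(theta)`` is assembled along the capsule surface
  and integrated into moving force, friction and drag, and the
  resulting net force accelerates the capsule.

Because smooth muscle contracts over tens of seconds while the capsule
crosses its own length in a few seconds, the tissue that has been inside
the footprint longest sits at the capsule's rear: the fore-aft asymmetry
of ``Ps`` over the rear ramp is what propels the capsule.

Friction at rest uses a stiction clamp (capped at the driving force) so
a capsule whose friction exceeds its moving force simply stays put
instead of chattering numerically.  The forward model contains no
randomness: identical configurations produce identical traces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .forces import DragModel, friction_force, moving_force
from .geometry import MM, CapsuleShape
from .stimulation import (DoseResponseParams, StimulusParams,
                          gaussian_footprint, max_contraction_pressure)
from .tissue import TissueParams, strain

__all__ = ["SolverSettings", "TissueField", "CapsuleModel",
           "SimulationResults", "SimulationError", "OutOfDomainError"]


class SimulationError(RuntimeError):
    """Numerical failure during time stepping (carries the failing time)."""


class OutOfDomainError(SimulationError):
    """The capsule left the maximum allowed tissue-grid extent."""


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping and discretisation controls (SI units).

    dt: Euler step (s).  grid_dx: lab-grid spacing (m).  margin_sigmas:
    grid margin on each side of the capsule, in footprint standard
    deviations.  quad_points: Simpson nodes along the capsule.
    decimation: record every k-th step.  tau_fall: decay time constant
    for a node leaving the footprint (None: same as the rising tau_s).
    hold_position: freeze the capsule (used for protocol emulation and
    field-integrator verification).  max_grid_nodes: hard cap before an
    out-of-domain error is raised.
    """

    dt: float = 1e-3
    grid_dx: float = 0.25 * MM
    margin_sigmas: float = 10.0
    quad_points: int = 501
    decimation: int = 10
    tau_fall: Optional[float] = None
    hold_position: bool = False
    max_grid_nodes: int = 2_000_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.grid_dx <= 0:
            raise ValueError("grid spacing must be positive")
        if self.decimation < 1:
            raise ValueError("decimation must be >= 1")
        if self.quad_points < 3:
            raise ValueError("need at least 3 quadrature points")
        if self.tau_fall is not None and self.tau_fall <= 0:
            raise ValueError("tau_fall must be positive")


@dataclass
class TissueField:
    """Lab-frame tissue state: grid (m), Ps (Pa), stretch clocks (s)."""

    grid: np.ndarray
    Ps: np.ndarray
    stretch_start: np.ndarray  # NaN where never strained
    engaged_prev: np.ndarray   # bool, strained at the previous step

    @classmethod
    def empty(cls, lo: float, hi: float, dx: float) -> "TissueField":
        n = int(np.ceil((hi - lo) / dx)) + 1
        grid = lo + dx * np.arange(n)
        return cls(grid=grid,
                   Ps=np.zeros(n),
                   stretch_start=np.full(n, np.nan),
                   engaged_prev=np.zeros(n, dtype=bool))

    def extend_right(self, hi: float, dx: float) -> None:
        n_new = int(np.ceil((hi - self.grid[-1]) / dx))
        if n_new <= 0:
            return
        new = self.grid[-1] + dx * np.arange(1, n_new + 1)
        self.grid = np.concatenate([self.grid, new])
        self.Ps = np.concatenate([self.Ps, np.zeros(n_new)])
        self.stretch_start = np.concatenate(
            [self.stretch_start, np.full(n_new, np.nan)])
        self.engaged_prev = np.concatenate(
            [self.engaged_prev, np.zeros(n_new, dtype=bool)])

    def extend_left(self, lo: float, dx: float) -> None:
        n_new = int(np.ceil((self.grid[0] - lo) / dx))
        if n_new <= 0:
            return
        new = self.grid[0] - dx * np.arange(n_new, 0, -1)
        self.grid = np.concatenate([new, self.grid])
        self.Ps = np.concatenate([np.zeros(n_new), self.Ps])
        self.stretch_start = np.concatenate(
            [np.full(n_new, np.nan), self.stretch_start])
        self.engaged_prev = np.concatenate(
            [np.zeros(n_new, dtype=bool), self.engaged_prev])


def _simpson_weights(x: np.ndarray) -> np.ndarray:
    """Composite Simpson weights for a uniform, odd-length grid."""
    n = len(x)
    h = x[1] - x[0]
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


class CapsuleModel:
    """Mechanistic model of an electrically propelled capsule.

    Assembles the geometry, passive tissue mechanics, stimulation and
    drag submodels into a forward simulator.  ``simulate(duration)``
    runs the fixed-step loop and returns a :class:`SimulationResults`.

    Parameters
    ----------
    shape, tissue, stimulus, drag : component parameter objects
    mass : float
        Capsule mass in kg.  Never reported for real telemetry capsules
        in the source experiments; treated as a calibration input.
    dose : DoseResponseParams, optional
        Dose-response coefficients (defaults to the measured ones).
    solver : SolverSettings, optional
    external_force : float, optional
        If set, replaces the tissue-derived moving force with a constant
        applied force (N).  A verification harness: with zero stimulus
        and mu = 0 the capsule then follows the closed-form linear drag
        ODE ``v(t) = (F/b)(1 - exp(-b t / m))``.
    grouping : str
        Dose-response grouping convention (see stimulation module).
    """

    def __init__(self, shape: CapsuleShape, tissue: TissueParams,
                 stimulus: StimulusParams, drag: DragModel, mass: float,
                 dose: DoseResponseParams = DoseResponseParams(),
                 solver: SolverSettings = SolverSettings(),
                 external_force: Optional[float] = None,
                 grouping: str = "ratio"):
        if mass <= 0:
            raise ValueError("capsule mass must be positive")
        if not (0.0 <= stimulus.electrode_offset <= shape.L):
            raise ValueError("electrode offset must lie within [0, L]")
        self.shape = shape
        self.tissue = tissue
        self.stimulus = stimulus
        self.drag = drag
        self.mass = mass
        self.dose = dose
        self.solver = solver
        self.external_force = external_force
        self.grouping = grouping

    # -- precomputed capsule-frame fields -----------------------------

    def _engagement_interval(self):
        """Local interval [x_lo, x_hi] where the capsule strains tissue."""
        thresh = (self.tissue.d0 / 2.0
                  if self.tissue.strain_mode == "diameter_ratio"
                  else self.tissue.d0)
        s = self.shape
        if s.r >= thresh:
            return 0.0, s.L
        if s.R <= thresh:
            return None
        # solve f(x) = thresh on the rear ramp, mirror for the front
        x_lo = -np.log(1.0 - (thresh - s.r) / (s.R - s.r)) / s.alpha
        return float(x_lo), float(s.L - x_lo)

    def _prepare(self):
        s = self.shape
        x_q = s.quadrature_grid(self.solver.quad_points)
        f_q = s.profile(x_q)
        df_q = s.dprofile(x_q)
        root = np.sqrt(1.0 + df_q * df_q)
        sin_theta = 1.0 / root  # sin(pi/2 - arctan f'), algebraic form
        area = f_q * root
        w = _simpson_weights(x_q)
        # dot-product weights reproducing forces.moving_force / friction_force
        w_move = 2.0 * np.pi * w * (df_q / root) * area
        w_fric = 2.0 * np.pi * self.tissue.mu * w * sin_theta * area
        eps_q = strain(s, x_q, self.tissue)
        # thin-wall prefactor folded with strain: Pi = coeff * spectrum(t)
        pi_coeff = np.where(eps_q > 0.0,
                            eps_q * 2.0 * self.tissue.h / (2.0 * f_q), 0.0)
        return x_q, sin_theta, w_move, w_fric, pi_coeff

    # -- main loop -----------------------------------------------------

    def simulate(self, duration: float, position0: float = 0.0,
                 record_every: Optional[int] = None) -> "SimulationResults":
        """Run the forward model for ``duration`` seconds.

        ``position0`` is the initial lab coordinate of the capsule's
        rear edge (m).  Deterministic: no randomness anywhere in the
        forward model.
        """
        if duration <= 0:
            raise ValueError("duration must be positive")
        sol = self.solver
        dt = sol.dt
        n_steps = int(round(duration / dt))
        decim = record_every if record_every is not None else sol.decimation

        s = self.shape
        stim = self.stimulus
        tis = self.tissue
        x_q, sin_theta_q, w_move, w_fric, pi_coeff = self._prepare()
        a1, a2, ainf = tis.amplitudes
        t1, t2 = tis.relax_taus
        tau_rise = tis.tau_s
        tau_fall = sol.tau_fall if sol.tau_fall is not None else tau_rise

        Pm = max_contraction_pressure(self.dose, stim, grouping=self.grouping)
        engage = self._engagement_interval()

        margin = sol.margin_sigmas * np.sqrt(stim.footprint_variance) + s.L
        field = TissueField.empty(position0 - margin,
                                  position0 + s.L + margin, sol.grid_dx)

        pos = float(position0)
        v = 0.0
        stiction_engaged = False
        rows = []

        for i in range(n_steps + 1):
            t = i * dt
            if not np.isfinite(pos) or not np.isfinite(v):
                raise SimulationError(
                    f"non-finite capsule state at t = {t:.6g} s")
            # keep the grid covering the capsule plus the footprint margin
            if pos + s.L + margin > field.grid[-1]:
                field.extend_right(pos + s.L + 2 * margin, sol.grid_dx)
            if pos - margin < field.grid[0]:
                field.extend_left(pos - 2 * margin, sol.grid_dx)
            if len(field.grid) > sol.max_grid_nodes:
                raise OutOfDomainError(
                    f"tissue grid exceeded {sol.max_grid_nodes} nodes "
                    f"at t = {t:.6g} s (capsule at {pos / MM:.1f} mm)")

            x0 = pos + stim.electrode_offset
            target = Pm * gaussian_footprint(field.grid, x0,
                                             stim.footprint_variance,
                                             stim.footprint_amplitude)

            # stretch clocks: start where the capsule newly strains tissue
            if engage is not None:
                engaged = ((field.grid >= pos + engage[0])
                           & (field.grid <= pos + engage[1]))
                newly = engaged & ~field.engaged_prev
                if np.any(newly):
                    field.stretch_start[newly] = t
                field.engaged_prev = engaged

            # pressures along the capsule surface
            xq_lab = pos + x_q
            Ps_q = np.interp(xq_lab, field.grid, field.Ps)
            start_filled = np.where(np.isnan(field.stretch_start), t,
                                    field.stretch_start)
            ts_q = np.maximum(t - np.interp(xq_lab, field.grid, start_filled),
                              0.0)
            Pi_q = pi_coeff * (a1 * np.exp(-ts_q / t1)
                               + a2 * np.exp(-ts_q / t2) + ainf)
            P1_q = np.maximum((Ps_q + Pi_q) * sin_theta_q, 0.0)

            if self.external_force is not None:
                F_m = self.external_force
            else:
                F_m = float(w_move @ P1_q)
            F_f_mag = float(w_fric @ P1_q)
            F_d = self.drag.b * v
            if v == 0.0:
                # stiction clamp: static friction balances the driving
                # force up to its kinetic magnitude
                F_f = float(np.clip(F_m, -F_f_mag, F_f_mag))
                if abs(F_m) <= F_f_mag and F_m != 0.0:
                    stiction_engaged = True
            else:
                F_f = float(np.copysign(F_f_mag, v))
            F_t = F_m - F_f - F_d
            a = 0.0 if sol.hold_position else F_t / self.mass

            if i % decim == 0 or i == n_steps:
                rows.append((t, pos, v, a, F_m, F_f, F_d, F_t))
            if i == n_steps:
                break

            # explicit Euler state update
            v_new = v + dt * a
            if v != 0.0 and v * v_new < 0.0 and abs(F_m) <= F_f_mag:
                v_new = 0.0  # friction stops the capsule, never reverses it
            if not sol.hold_position:
                pos = pos + dt * v
            v = v_new
            # tissue field relaxes toward its (moving) target
            tau = np.where(target > field.Ps, tau_rise, tau_fall)
            field.Ps = field.Ps + dt * (target - field.Ps) / tau

        data = np.asarray(rows, dtype=float)
        return SimulationResults(self, data, field, duration)


class SimulationResults:
    """Trace and summary statistics of one forward simulation.

    ``trace`` is a DataFrame in reporting units (mm, s, mN) with the
    net force column recomputed from the converted components so the
    force-balance identity holds exactly in the emitted table.
    """

    _raw_columns = ("t", "pos", "v", "a", "F_m", "F_f", "F_d", "F_t")

    def __init__(self, model: CapsuleModel, data: np.ndarray,
                 field: TissueField, duration: float):
        self.model = model
        self._data = data
        self.field = field
        self.duration = duration
        self.stiction_engaged = bool(
            np.any((data[:, 2] == 0.0) & (data[:, 4] != 0.0)
                   & (data[:, 7] == 0.0)))

    @property
    def trace(self) -> pd.DataFrame:
        d = self._data
        fm = d[:, 4] / 1e-3
        ff = d[:, 5] / 1e-3
        fd = d[:, 6] / 1e-3
        return pd.DataFrame({
            "t_s": d[:, 0],
            "x_mm": d[:, 1] / MM,
            "v_mm_s": d[:, 2] / MM,
            "a_mm_s2": d[:, 3] / MM,
            "Fm_mN": fm, "Ff_mN": ff, "Fd_mN": fd,
            "Ft_mN": fm - ff - fd,
        })

    # -- summary statistics -------------------------------------------

    def steady_velocity(self, window: float = 10.0) -> float:
        """Mean velocity (m/s) over the trailing ``window`` seconds."""
        t = self._data[:, 0]
        if window > t[-1] - t[0]:
            raise ValueError("averaging window longer than the trace")
        sel = t >= t[-1] - window
        return float(np.mean(self._data[sel, 2]))

    def initial_acceleration(self, window: float = 2.0) -> float:
        """Mean net acceleration (m/s^2) over the first ``window`` seconds."""
        t = self._data[:, 0]
        if window > t[-1] - t[0]:
            raise ValueError("averaging window longer than the trace")
        sel = t <= window
        i_last = np.nonzero(sel)[0][-1]
        dv = self._data[i_last, 2] - self._data[0, 2]
        return float(dv / (self._data[i_last, 0] - self._data[0, 0]))

    @property
    def displacement(self) -> float:
        """Net displacement (m) over the run."""
        return float(self._data[-1, 1] - self._data[0, 1])

    @property
    def final_velocity(self) -> float:
        return float(self._data[-1, 2])

    def to_dict(self) -> dict:
        w = min(10.0, 0.5 * self.duration)
        return {
            "duration_s": self.duration,
            "displacement_mm": self.displacement / MM,
            "final_velocity_mm_s": self.final_velocity / MM,
            "steady_velocity_mm_s": self.steady_velocity(w) / MM,
            "steady_window_s": w,
            "initial_acceleration_mm_s2":
                self.initial_acceleration(min(10.0, 0.5 * self.duration)) / MM,
            "stiction_engaged": self.stiction_engaged,
        }

    def summary(self) -> str:
        d = self.to_dict()
        buf = io.StringIO()
        buf.write("Capsule locomotion simulation\n")
        buf.write(f"  duration:             {d['duration_s']:.3g} s\n")
        buf.write(f"  displacement:         {d['displacement_mm']:.4g} mm\n")
        buf.write(f"  steady velocity:      {d['steady_velocity_mm_s']:.4g} "
                  f"mm/s (trailing {d['steady_window_s']:.3g} s)\n")
        buf.write(f"  initial acceleration: "
                  f"{d['initial_acceleration_mm_s2']:.4g} mm/s^2\n")
        buf.write(f"  stiction engaged:     {d['stiction_engaged']}\n")
        return buf.getvalue()

    def plot(self, ax=None):
        """Plot position and velocity versus time (matplotlib)."""
        import matplotlib.pyplot as plt
        tr = self.trace
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(tr["t_s"], tr["x_mm"], label="position (mm)")
        ax2 = ax.twinx()
        ax2.plot(tr["t_s"], tr["v_mm_s"], color="C1", label="velocity (mm/s)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position (mm)")
        ax2.set_ylabel("velocity (mm/s)")
        return ax
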