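"""Synthetic contraction-measurement data.

Emulates the balloon-catheter contraction experiments used to calibrate
the stimulation model, so the dose-response and rising-time estimators
can be exercised and validated without any external data:

* peak-pressure tables over a (frequency, amplitude) grid — the true
  dose-response surface plus additive Gaussian measurement noise;
* first-order rise curves with per-sample rising time constants drawn
  from a truncated normal around the measured 17.3 +- 8.3 s.

Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .stimulation import DoseResponseParams, _dose_surface_kpa

__all__ = ["SyntheticProtocol", "gen_peak_pressure_table", "gen_rise_curves",
           "write_table", "read_table"]


@dataclass(frozen=True)
class SyntheticProtocol:
    """Protocol of the emulated contraction experiments.

    Defaults mirror the source protocol: stimulus frequencies 10/20/40 Hz
    at a fixed 5 ms pulse, amplitudes stepped 2-10 V, four tissue samples
    per cell, peak-pressure noise 0.2 kPa, and rising time constants
    17.3 +- 8.3 s truncated below at 1 s (nonpositive time constants are
    unphysical).
    """

    freq_levels: Tuple[float, ...] = (10.0, 20.0, 40.0)
    amp_levels: Tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
    replicates: int = 4
    noise_sd_kpa: float = 0.2
    true_params: DoseResponseParams = field(default_factory=DoseResponseParams)
    tau_s_mean: float = 17.3
    tau_s_sd: float = 8.3
    tau_s_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.freq_levels or not self.amp_levels:
            raise ValueError("frequency and amplitude levels must be nonempty")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per cell")
        if self.noise_sd_kpa < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.tau_s_mean <= 0 or self.tau_s_sd < 0 or self.tau_s_min <= 0:
            raise ValueError("tau_s protocol values must be positive")


def gen_peak_pressure_table(protocol: SyntheticProtocol) -> pd.DataFrame:
    """Peak contraction pressures on the stimulus grid, with noise.

    One row per (frequency, amplitude, replicate):
    ``pressure = dose_surface(fs, As) + N(0, noise_sd)`` in kPa.
    """
    rng = np.random.default_rng(protocol.seed)
    fs, As = np.meshgrid(protocol.freq_levels, protocol.amp_levels,
                         indexing="ij")
    fs = np.repeat(fs.ravel(), protocol.replicates)
    As = np.repeat(As.ravel(), protocol.replicates)
    truth = _dose_surface_kpa(fs, As, protocol.true_params.as_array())
    noise = rng.normal(0.0, protocol.noise_sd_kpa, size=fs.shape)
    return pd.DataFrame({"fs_hz": fs, "as_volt": As,
                         "pressure_kpa": truth + noise})


def _sample_tau(rng, protocol: SyntheticProtocol, n: int) -> np.ndarray:
    """Truncated-normal rising time constants (rejection sampling)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(protocol.tau_s_mean, protocol.tau_s_sd,
                          size=2 * (n - filled))
        draw = draw[draw > protocol.tau_s_min][: n - filled]
        out[filled:filled + len(draw)] = draw
        filled += len(draw)
    return out


def gen_rise_curves(protocol: SyntheticProtocol, n_curves: int = 20,
                    t_max: float = 90.0, dt: float = 0.5) -> pd.DataFrame:
    """Per-sample contraction transients with sampled time constants.

    Each curve is ``P(t) = Pm (1 - exp(-t/tau))`` sampled on a uniform
    time grid with additive Gaussian noise; the plateau ``Pm`` comes
    from the true dose-response surface at 6 V, cycling through the
    protocol's frequency levels.  The generating ``tau_true_s`` and
    ``plateau_kpa`` are included per sample for recovery testing.
    """
    if n_curves < 1:
        raise ValueError("need at least one curve")
    rng = np.random.default_rng(protocol.seed)
    taus = _sample_tau(rng, protocol, n_curves)
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    frames = []
    for i in range(n_curves):
        fs = protocol.freq_levels[i % len(protocol.freq_levels)]
        pm = float(_dose_surface_kpa(fs, 6.0, protocol.true_params.as_array()))
        p = pm * (1.0 - np.exp(-t / taus[i]))
        p = p + rng.normal(0.0, protocol.noise_sd_kpa, size=t.shape)
        frames.append(pd.DataFrame({
            "sample": i, "fs_hz": fs, "t_s": t, "pressure_kpa": p,
            "tau_true_s": taus[i], "plateau_kpa": pm,
        }))
    return pd.concat(frames, ignore_index=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a measurement table as CSV at full double precision."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read a measurement table written by :func:`write_table`."""
    return pd.read_csv(path, float_precision="round_trip")
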