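import numpy as np
import pytest

from capsulesim import (DoseResponseModel, DoseResponseParams, RiseTimeModel,
                        StimulusParams, gaussian_footprint,
                        max_contraction_pressure, transient_pressure)
from capsulesim.stimulation import DoseResponseError
from capsulesim.synthetic import SyntheticProtocol, gen_peak_pressure_table

KPA = 1e3
TRUE = (0.24, 1.18, 4.97, 3.72)


def _surface_kpa(fs, As, a=0.24, b=1.18, c=4.97, k=3.72):
    """Independent literal evaluation of the dose-response surface."""
    return (a * fs + b) / (1.0 + (As / c) ** (-k))


def stim(amp, freq=10.0):
    return StimulusParams.from_config_units(amp, freq, 5.0, 5.0)


class TestMaxContractionPressure:
    def test_half_maximum_at_midpoint_amplitude(self):
        dose = DoseResponseParams()
        got = max_contraction_pressure(dose, stim(4.97, 10.0))
        assert got == pytest.approx(0.5 * (0.24 * 10 + 1.18) * KPA, rel=1e-12)

    def test_saturation_limit(self):
        dose = DoseResponseParams()
        got = max_contraction_pressure(dose, stim(1e6, 10.0))
        assert got == pytest.approx((0.24 * 10 + 1.18) * KPA, rel=1e-6)

    def test_zero_amplitude_gives_zero(self):
        assert max_contraction_pressure(DoseResponseParams(), stim(0.0)) == 0.0

    def test_monotone_in_amplitude_and_frequency(self):
        dose = DoseResponseParams()
        amps = np.linspace(0.5, 12.0, 24)
        p_a = [max_contraction_pressure(dose, stim(a, 20.0)) for a in amps]
        assert np.all(np.diff(p_a) > 0)
        freqs = np.linspace(5.0, 40.0, 15)
        p_f = [max_contraction_pressure(dose, stim(6.0, f)) for f in freqs]
        assert np.all(np.diff(p_f) > 0)

    def test_matches_literal_formula(self):
        dose = DoseResponseParams()
        for fs, As in [(10, 2), (20, 6), (40, 10), (10, 4.97)]:
            assert max_contraction_pressure(dose, stim(As, fs)) == (
                pytest.approx(_surface_kpa(fs, As) * KPA, rel=1e-12))


class TestTransientPressure:
    def test_boundary_and_63_2_percent(self):
        tau = 17.3
        assert transient_pressure(2.0, 0.0, tau) == 0.0
        assert transient_pressure(2.0, tau, tau) == pytest.approx(
            2.0 * (1 - np.exp(-1.0)))
        assert transient_pressure(2.0, tau, tau) / 2.0 == pytest.approx(
            0.632, abs=2e-4)
        assert transient_pressure(2.0, 1e6, tau) == pytest.approx(2.0)

    def test_ode_residual(self):
        # dPs/dt + Ps/tau - Pm/tau must vanish along the closed form
        Pm, tau = 3.0, 17.3
        t = np.linspace(0.0, 100.0, 57)
        Ps = transient_pressure(Pm, t, tau)
        dPs = (Pm / tau) * np.exp(-t / tau)  # analytic derivative
        resid = dPs + Ps / tau - Pm / tau
        assert np.max(np.abs(resid)) < 1e-9


class TestGaussianFootprint:
    def test_peak_symmetry_and_e_folding(self):
        omega = 0.22e-4  # m^2
        x0 = 0.05
        assert gaussian_footprint(x0, x0, omega) == pytest.approx(1.4)
        d = 3e-3
        assert gaussian_footprint(x0 + d, x0, omega) == pytest.approx(
            gaussian_footprint(x0 - d, x0, omega))
        # (x - x0)^2 = 2 omega -> amplitude / e
        assert gaussian_footprint(x0 + np.sqrt(2 * omega), x0, omega) == (
            pytest.approx(1.4 / np.e, rel=1e-12))


class TestDoseResponseFit:
    def _table(self, noise_sd, seed=0, replicates=1):
        return gen_peak_pressure_table(SyntheticProtocol(
            noise_sd_kpa=noise_sd, seed=seed, replicates=replicates))

    def test_noiseless_recovery(self):
        res = DoseResponseModel(self._table(0.0)).fit()
        rel = np.abs(res.params - np.array(TRUE)) / np.array(TRUE)
        assert np.max(rel) <= 1e-4
        assert res.rms < 1e-8

    def test_rank_deficient_designs_rejected(self):
        import pandas as pd
        tab = self._table(0.0, replicates=4)
        single_amp = tab[tab.as_volt == 6.0]
        with pytest.raises(DoseResponseError, match="rank deficient"):
            DoseResponseModel(single_amp.reset_index(drop=True))
        flat = tab.copy()
        flat["pressure_kpa"] = 3.0
        with pytest.raises(DoseResponseError, match="unidentifiable"):
            DoseResponseModel(flat)
        with pytest.raises(DoseResponseError, match="at least 8 rows"):
            DoseResponseModel(tab.iloc[:5])

    def test_noisy_fits_within_monte_carlo_bounds(self):
        """Median coefficient errors at sigma = 0.2 kPa stay within the
        linearized-theory bound computed by an independent oracle."""
        # oracle: standard errors from a finite-difference Jacobian of the
        # literal surface at the true coefficients
        proto = SyntheticProtocol(noise_sd_kpa=0.2, seed=1, replicates=4)
        fs, As = np.meshgrid(proto.freq_levels, proto.amp_levels, indexing="ij")
        fs = np.repeat(fs.ravel(), proto.replicates)
        As = np.repeat(As.ravel(), proto.replicates)
        theta = np.array(TRUE)
        J = np.empty((len(fs), 4))
        for j in range(4):
            dth = np.zeros(4)
            dth[j] = 1e-6 * theta[j]
            J[:, j] = (_surface_kpa(fs, As, *(theta + dth))
                       - _surface_kpa(fs, As, *(theta - dth))) / (2 * dth[j])
        se = 0.2 * np.sqrt(np.diag(np.linalg.inv(J.T @ J)))
        errors = []
        for rep in range(50):
            tab = self._table(0.2, seed=100 + rep, replicates=4)
            res = DoseResponseModel(tab).fit()
            errors.append(np.abs(res.params - theta))
        med = np.median(np.array(errors), axis=0)
        # median |error| of a normal estimator is ~0.674 SE; allow 2 SE
        assert np.all(med < 2.0 * se)

    def test_standard_errors_reported(self):
        res = DoseResponseModel(self._table(0.2, seed=3, replicates=4)).fit()
        assert res.bse.shape == (4,)
        assert np.all(res.bse > 0)
        assert "freq_slope" in res.summary()


class TestRiseTimeModel:
    def test_noiseless_recovery(self):
        t = np.arange(0.0, 90.0, 0.5)
        p = 2.5 * (1 - np.exp(-t / 17.3))
        res = RiseTimeModel(t, p).fit()
        assert res.tau_s == pytest.approx(17.3, rel=1e-3)
        assert res.plateau == pytest.approx(2.5, rel=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            RiseTimeModel(np.array([0.0, 1.0, 0.5]), np.array([0.0, 1.0, 2.0]))
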