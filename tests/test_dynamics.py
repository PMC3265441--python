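import numpy as np
import pytest

from capsulesim import (CapsuleModel, CapsuleShape, DragModel,
                        OutOfDomainError, SolverSettings, StimulusParams,
                        TissueParams, max_contraction_pressure, preset_config)


def thin_cylinder_model(external_force=None, mass=0.02, b=0.1, dt=1e-3):
    """Capsule thinner than the resting lumen, no stimulus: tissue-free.

    With ``external_force`` set this reduces to the linear drag ODE
    m dv/dt = F - b v, which has the closed form v(t) = (F/b)(1-e^{-bt/m}).
    """
    shape = CapsuleShape.from_mm(2.5, 2.5, 0.3, 26.0)
    tissue = TissueParams.from_mm(8.0, 0.6, mu=0.0)
    stim = StimulusParams.from_config_units(0.0, 10.0, 5.0, 5.0)
    return CapsuleModel(shape, tissue, stim, DragModel.constant(b), mass=mass,
                        solver=SolverSettings(dt=dt),
                        external_force=external_force)


class TestStep:
    def test_zero_stimulus_thin_capsule_stays_at_rest(self):
        res = thin_cylinder_model().simulate(0.5)
        d = res.trace
        assert np.all(d[["x_mm", "v_mm_s", "a_mm_s2",
                         "Fm_mN", "Ff_mN", "Fd_mN", "Ft_mN"]].to_numpy() == 0.0)
        assert d["t_s"].iloc[-1] == pytest.approx(0.5)

    def test_field_reaches_63_2_percent_at_tau_s(self, type1_config):
        """Stationary capsule: the per-node field integrator must match the
        scalar first-order closed form — 63.2% of target at t = tau_s."""
        cfg = type1_config.replace(solver={"dt_s": 0.005,
                                           "hold_position": True})
        tau = cfg.tissue.tau_s
        model = cfg.build_model()
        res = model.simulate(tau)
        x0 = cfg.stimulus.electrode_offset  # capsule at position 0
        node = np.argmin(np.abs(res.field.grid - x0))
        pm = max_contraction_pressure(cfg.dose, cfg.stimulus)
        from capsulesim import gaussian_footprint
        target = pm * gaussian_footprint(res.field.grid[node], x0,
                                         cfg.stimulus.footprint_variance)
        assert res.field.Ps[node] / target == pytest.approx(0.632, abs=1e-3)

    def test_forced_constant_force_matches_closed_form(self):
        F, b, m = 1e-3, 0.1, 0.02
        res = thin_cylinder_model(external_force=F, mass=m, b=b).simulate(1.5)
        d = res._data
        t, v = d[:, 0], d[:, 2]
        closed = (F / b) * (1.0 - np.exp(-b * t / m))
        sel = t > 0
        assert np.max(np.abs(v[sel] - closed[sel]) / closed[sel]) < 5e-3

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            thin_cylinder_model(mass=0.0)
        with pytest.raises(ValueError):
            SolverSettings(dt=0.0)
        shape = CapsuleShape.from_mm(3.0, 5.5, 0.3, 26.0)
        stim = StimulusParams.from_config_units(6.0, 10.0, 5.0, 30.0)
        with pytest.raises(ValueError, match="electrode offset"):
            CapsuleModel(shape, TissueParams.from_mm(8.0, 0.6), stim,
                         DragModel.constant(0.5), mass=3.8e-3)

    def test_grid_overflow_raises(self, type1_config):
        cfg = type1_config.replace(solver={"dt_s": 0.001})
        model = cfg.build_model()
        model.solver = SolverSettings(max_grid_nodes=100)
        with pytest.raises(OutOfDomainError):
            model.simulate(1.0)


class TestSimulate:
    def test_determinism_bit_identical(self, type1_config):
        m1 = type1_config.build_model()
        m2 = type1_config.build_model()
        d1 = m1.simulate(3.0)._data
        d2 = m2.simulate(3.0)._data
        assert np.array_equal(d1, d2)

    def test_force_balance_identity_every_row(self, type1_config):
        tr = type1_config.build_model().simulate(8.0).trace
        lhs = tr["Ft_mN"].to_numpy()
        rhs = (tr["Fm_mN"] - tr["Ff_mN"] - tr["Fd_mN"]).to_numpy()
        assert np.array_equal(lhs, rhs)

    def test_field_never_exceeds_target(self, type1_config):
        cfg = type1_config
        res = cfg.build_model().simulate(6.0)
        pm = max_contraction_pressure(cfg.dose, cfg.stimulus)
        peak_target = pm * cfg.stimulus.footprint_amplitude
        assert np.max(res.field.Ps) <= peak_target * (1 + 1e-12)

    def test_type3_control_does_not_move(self, type1_config):
        cfg = type1_config.replace(shape={"r_mm": 4.0})
        res = cfg.build_model().simulate(15.0)
        assert res.displacement == 0.0
        assert res.final_velocity == 0.0
        assert res.stiction_engaged

    def test_type1_moves_forward(self, type1_config):
        res = type1_config.build_model().simulate(15.0)
        assert res.displacement > 0.0
        assert res.steady_velocity(3.0) > 0.0


class TestSummaryStatistics:
    def test_steady_velocity_terminal_value(self):
        F, b = 1e-3, 0.1
        res = thin_cylinder_model(external_force=F, b=b).simulate(2.0)
        assert res.steady_velocity(0.3) == pytest.approx(F / b, rel=1e-2)

    def test_window_validation(self):
        res = thin_cylinder_model().simulate(0.5)
        with pytest.raises(ValueError):
            res.steady_velocity(1.0)
        with pytest.raises(ValueError):
            res.initial_acceleration(1.0)

    def test_summary_text(self, type1_config):
        res = type1_config.build_model().simulate(5.0)
        s = res.summary()
        assert "steady velocity" in s and "displacement" in s
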