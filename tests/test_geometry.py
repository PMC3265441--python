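import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsulesim import CapsuleShape, surface_integral

# scale-free shape parameters (the profile formula is unit covariant, so
# these tests work directly in millimetres)
shapes = st.builds(
    CapsuleShape,
    r=st.floats(0.5, 5.0),
    R=st.floats(5.0, 8.0),
    alpha=st.floats(0.05, 2.0),
    L=st.floats(10.0, 40.0),
)


class TestProfile:
    def test_tip_values_and_hand_evaluated_midpoint(self):
        s = CapsuleShape(r=3.0, R=5.5, alpha=0.3, L=26.0)
        assert s.profile(0.0) == pytest.approx(3.0, abs=1e-12)
        assert s.profile(26.0) == pytest.approx(3.0, abs=1e-12)
        # direct evaluation of (R-r)(1-exp(-alpha x)) + r at x = 13
        expected = 2.5 * (1.0 - math.exp(-0.3 * 13.0)) + 3.0
        assert s.profile(13.0) == pytest.approx(expected, rel=1e-12)

    def test_large_alpha_approaches_cylinder(self):
        s = CapsuleShape(r=3.0, R=5.5, alpha=50.0, L=26.0)
        assert s.profile(13.0) == pytest.approx(5.5, abs=1e-9)

    def test_domain_error(self, shape_type1):
        with pytest.raises(ValueError):
            shape_type1.profile(-1e-3)
        with pytest.raises(ValueError):
            shape_type1.profile(shape_type1.L * 1.01)

    @pytest.mark.parametrize("kw", [
        dict(r=0.0, R=5.5, alpha=0.3, L=26.0),
        dict(r=6.0, R=5.5, alpha=0.3, L=26.0),
        dict(r=3.0, R=5.5, alpha=-0.3, L=26.0),
        dict(r=3.0, R=5.5, alpha=0.3, L=0.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            CapsuleShape(**kw)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(shape=shapes, frac=st.floats(0.0, 1.0))
    def test_mirror_symmetry_and_bounds(self, shape, frac):
        x = frac * shape.L
        f = float(shape.profile(x))
        assert f == pytest.approx(float(shape.profile(shape.L - x)), rel=1e-9)
        assert shape.r - 1e-12 <= f < shape.R + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shape=shapes)
    def test_monotone_ramps(self, shape):
        x = np.linspace(0.0, shape.L / 2.0, 200)
        f = shape.profile(x)
        assert np.all(np.diff(f) >= -1e-12)
        f_front = shape.profile(shape.L - x)
        assert np.all(np.diff(f_front) >= -1e-12)


class TestSlopeAngle:
    # the fixture shape is SI (L = 26 mm = 0.026 m)

    def test_flat_mid_region(self, shape_type1):
        # exactly pi/2 at the midpoint (averaged one-sided derivative)
        assert shape_type1.slope_angle(shape_type1.L / 2) == np.pi / 2
        # nearly pi/2 anywhere on the flat mid-body (f' ~ 0)
        assert shape_type1.slope_angle(13.0e-3) == pytest.approx(
            np.pi / 2, abs=0.02)

    def test_ramp_signs(self, shape_type1):
        assert shape_type1.slope_angle(1.0e-3) < np.pi / 2  # rising rear ramp
        assert shape_type1.slope_angle(25e-3) > np.pi / 2  # falling front ramp

    def test_matches_finite_difference(self, shape_type1):
        L = shape_type1.L
        x = np.linspace(0.002 * L, 0.998 * L, 401)
        x = x[np.abs(x - L / 2) > 0.004 * L]  # avoid the C1 kink
        h = 1e-9
        fd = (shape_type1.profile(x + h) - shape_type1.profile(x - h)) / (2 * h)
        theta_fd = np.pi / 2 - np.arctan(fd)
        assert np.max(np.abs(theta_fd - shape_type1.slope_angle(x))) < 1e-6


class TestInternalVolume:
    def test_cylinder_closed_forms(self):
        cyl = CapsuleShape(r=4.0, R=4.0, alpha=0.3, L=26.0)
        assert cyl.internal_volume() == pytest.approx(np.pi * 16 * 26, rel=1e-12)
        nearly = CapsuleShape(r=3.0, R=5.5, alpha=100.0, L=26.0)
        assert nearly.internal_volume() == pytest.approx(
            np.pi * 5.5**2 * 26, rel=1e-3)

    def test_against_brute_force_slicing(self, shape_type1):
        # midpoint rule with 10^6 slices as the independent oracle
        n = 1_000_000
        dx = shape_type1.L / n
        xm = (np.arange(n) + 0.5) * dx
        oracle = np.pi * np.sum(shape_type1.profile(xm) ** 2) * dx
        assert shape_type1.internal_volume() == pytest.approx(oracle, rel=1e-4)

    def test_monotone_in_r_and_alpha(self):
        base = dict(R=5.5, L=26.0)
        vols_r = [CapsuleShape(r=r, alpha=0.3, **base).internal_volume()
                  for r in (2.0, 3.0, 4.0, 5.0)]
        assert np.all(np.diff(vols_r) > 0)
        vols_a = [CapsuleShape(r=3.0, alpha=a, **base).internal_volume()
                  for a in (0.1, 0.3, 0.6, 1.2)]
        assert np.all(np.diff(vols_a) > 0)


class TestSurfaceIntegral:
    def test_zero_pressure(self, shape_type1):
        assert surface_integral(shape_type1, lambda x: 0.0 * x) == 0.0

    def test_constant_pressure_on_cylinder(self):
        cyl = CapsuleShape(r=4.0, R=4.0, alpha=0.3, L=26.0)
        c = 2.5
        expected = 2 * np.pi * 4.0 * 26.0 * c  # lateral area x pressure
        got = surface_integral(cyl, lambda x: np.full_like(x, c))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_refinement_oracle(self, shape_type1):
        p = lambda x: 1.0 + np.sin(0.7 * x) ** 2 + 0.1 * x
        coarse = surface_integral(shape_type1, p, n=501)
        fine = surface_integral(shape_type1, p, n=5001)
        assert coarse == pytest.approx(fine, rel=1e-3)

    def test_linearity(self, shape_type1):
        p1 = lambda x: np.cos(x / 5.0) ** 2
        p2 = lambda x: 0.2 * x
        lhs = surface_integral(shape_type1, lambda x: 2 * p1(x) + 3 * p2(x))
        rhs = (2 * surface_integral(shape_type1, p1)
               + 3 * surface_integral(shape_type1, p2))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_nonfinite_pressure_rejected(self, shape_type1):
        with pytest.raises(FloatingPointError):
            surface_integral(shape_type1, lambda x: np.full_like(x, np.nan))
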