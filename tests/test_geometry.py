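"""Channel geometry: profiles, offset surfaces and derived scalars."""

import math

import numpy as np
import pytest

from celltransit import (
    AxisymChannel,
    RectChannel,
    axisym_radius_at,
    constricted_region_length,
    contact_angle_first_contact,
    equal_area_width,
    equal_dh_width,
    hydraulic_diameter,
    rect_half_width_at,
    rect_height_at,
    squeeze_length,
)
from celltransit.geometry import GeometryError, OutOfDomainError


def _offset_wall_oracle(arc_center, arc_radius, delta, x, below):
    """Independent offset-surface construction: the lateral position y at
    station x whose minimum distance to the (densely sampled, refined)
    actual arc equals delta."""
    from scipy.optimize import minimize_scalar

    cx, cy = arc_center

    def dist(y):
        f = lambda p: math.hypot(x - (cx + arc_radius * math.cos(p)),
                                 y - (cy + arc_radius * math.sin(p)))
        res = minimize_scalar(f, bounds=(math.pi, 2 * math.pi),
                              method="bounded",
                              options={"xatol": 1e-14})
        return res.fun

    lo, hi = 0.2, below  # [axis side, actual wall]; distance falls toward wall
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if dist(mid) > delta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestAxisymChannel:
    def test_imaginary_throat_radius(self, axisym_channel):
        assert axisym_radius_at(axisym_channel, 0.0, True) == pytest.approx(2.75)

    def test_pipe_radius_outside_constriction(self, axisym_channel):
        assert axisym_radius_at(axisym_channel, -40.0) == pytest.approx(6.0)

    def test_offset_arc_matches_independent_construction(self, axisym_channel):
        ch = axisym_channel
        for x in (2.0, 5.0, 9.0):
            y_actual = ch.arc_center_r - math.sqrt(ch.r_con**2 - x * x)
            oracle = _offset_wall_oracle(
                (0.0, ch.arc_center_r), ch.r_con, ch.delta, x, below=y_actual
            )
            assert ch.radius_at(x, True) == pytest.approx(oracle, abs=1e-8)

    def test_constricted_region_length(self, axisym_channel):
        assert constricted_region_length(axisym_channel) == pytest.approx(26.0)

    def test_no_constriction_limit(self):
        ch = AxisymChannel(r_min=6.0, delta=0.0)
        assert constricted_region_length(ch) == pytest.approx(0.0)

    def test_constricted_length_other_radius_vs_rootfind(self):
        ch = AxisymChannel(r_con=16.15)
        # root-find where the offset arc meets the pipe radius
        from scipy.optimize import brentq

        f = lambda x: ch.radius_at(x, True) - ch.r_pipe + 1e-15
        x_end = brentq(lambda x: (ch.arc_center_r
                                  - math.sqrt((ch.r_con + ch.delta) ** 2 - x * x)
                                  - ch.r_pipe), 0.1, ch.r_con)
        assert constricted_region_length(ch) == pytest.approx(2 * x_end, rel=1e-12)

    def test_profile_continuous_and_offset_inside(self, axisym_channel):
        xs = np.linspace(-49.9, 99.9, 4001)
        r_act = axisym_channel.radius_at(xs)
        r_im = axisym_channel.radius_at(xs, True)
        assert np.all(np.abs(np.diff(r_act)) < 0.05)
        assert np.all(r_im <= r_act + 1e-12)

    def test_out_of_domain(self, axisym_channel):
        with pytest.raises(OutOfDomainError):
            axisym_channel.radius_at(-60.0)

    def test_invalid_parameters(self):
        with pytest.raises(GeometryError):
            AxisymChannel(r_min=7.0)  # throat wider than pipe


class TestRectChannel:
    def test_imaginary_throat_half_width(self, control_channel):
        assert rect_half_width_at(control_channel, 0.0, True) == pytest.approx(2.084)

    def test_full_width_upstream(self, control_channel):
        assert rect_half_width_at(control_channel, -45.0) == pytest.approx(11.18)

    def test_offset_arc_matches_independent_construction(self, control_channel):
        ch = control_channel
        for x in (3.0, 8.0):
            y_actual = ch.arc_center_y - math.sqrt(ch.R_con**2 - x * x)
            oracle = _offset_wall_oracle(
                (0.0, ch.arc_center_y), ch.R_con, ch.delta, x, below=y_actual
            )
            assert ch.half_width_at(x, True) == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize(
        "x,expected",
        [(-45.0, 8.2), (0.0, 7.2), (-37.585, 7.7)],  # ramp midpoint is linear
    )
    def test_height_ramp(self, x, expected):
        ch = RectChannel(H=7.2)
        assert rect_height_at(ch, x) == pytest.approx(expected)

    def test_height_constant_when_tall(self):
        ch = RectChannel(H=12.2)
        xs = np.linspace(-49, 99, 50)
        assert np.allclose(ch.height_at(xs), 12.2)

    def test_profiles_continuous_and_offset_inside(self, control_channel):
        xs = np.linspace(-49.9, 99.9, 4001)
        for ch in (control_channel, RectChannel(H=7.2, R_con=16.15, W_con=3.112)):
            hw_act = ch.half_width_at(xs)
            hw_im = ch.half_width_at(xs, True)
            assert np.all(np.abs(np.diff(hw_act)) < 0.1)
            assert np.all(np.abs(np.diff(hw_im)) < 0.1)
            assert np.all(hw_im <= hw_act + 1e-12)
            assert np.all(ch.height_at(xs, True) <= ch.height_at(xs) + 1e-12)

    def test_half_width_minimal_at_throat(self, control_channel):
        xs = np.linspace(-49.9, 99.9, 2001)
        hw = control_channel.half_width_at(xs, True)
        assert control_channel.half_width_at(0.0, True) <= hw.min() + 1e-12

    def test_invalid_parameters(self):
        with pytest.raises(GeometryError):
            RectChannel(H=8.2, W_con=25.0)  # throat wider than channel
        with pytest.raises(GeometryError):
            RectChannel(H=0.1)


class TestMatchingWidths:
    @pytest.mark.parametrize(
        "h,w,expected",
        [(8.2, 4.368, 5.70), (7.2, 4.717, 5.70), (10.2, 3.955, 5.70)],
    )
    def test_printed_equal_dh_pairs(self, h, w, expected):
        assert round(hydraulic_diameter(h, w), 2) == expected

    def test_square_duct(self):
        assert hydraulic_diameter(3.3, 3.3) == pytest.approx(3.3)

    def test_symmetry(self):
        assert hydraulic_diameter(5.0, 9.0) == hydraulic_diameter(9.0, 5.0)

    @pytest.mark.parametrize(
        "h,r,expected,nd", [(8.2, 2.85, 3.112, 3), (10.0, 2.85, 2.552, 3)]
    )
    def test_equal_area_width(self, h, r, expected, nd):
        assert round(equal_area_width(h, r), nd) == expected

    @pytest.mark.parametrize(
        "h,d,expected", [(8.2, 5.7, 4.368), (10.2, 5.7, 3.955)]
    )
    def test_equal_dh_width(self, h, d, expected):
        assert round(equal_dh_width(h, d), 3) == expected

    def test_equal_dh_square_limit(self):
        assert equal_dh_width(5.7, 5.7) == pytest.approx(5.7)

    def test_equal_dh_infeasible(self):
        with pytest.raises(GeometryError):
            equal_dh_width(2.0, 5.7)

    def test_errors_on_nonpositive(self):
        with pytest.raises(GeometryError):
            hydraulic_diameter(-1.0, 2.0)


class TestFirstContact:
    @pytest.mark.parametrize(
        "kw,expected,nd",
        [
            (dict(W_con=3.112), 12.4, 1),
            (dict(W_con=4.368), 10.8, 1),
            (dict(W_con=5.7), 8.80, 2),
            (dict(R_con=16.15), 8.60, 2),
            (dict(R_con=42.15), 13.2, 1),
        ],
    )
    def test_printed_squeeze_lengths(self, kw, expected, nd):
        ch = RectChannel(H=8.2, **kw)
        assert round(squeeze_length(ch, 4.0).s, nd) == expected

    def test_control_contact_angle(self, control_channel):
        theta = contact_angle_first_contact(control_channel, 4.0)
        assert theta == pytest.approx(math.atan2(29.709, 10.8405), abs=1e-3)
        assert theta == pytest.approx(1.221, abs=1e-3)

    def test_angle_approaches_pi_half_at_throat_tangency(self):
        ch = RectChannel(H=8.2, W_con=8.199)  # first contact almost at throat
        assert contact_angle_first_contact(ch, 4.0) == pytest.approx(
            math.pi / 2, abs=0.05
        )

    def test_no_contact_for_wide_throat(self):
        ch = RectChannel(H=10.0, W_con=8.4)
        fc = squeeze_length(ch, 4.0)
        assert not fc.contact_exists
        with pytest.raises(GeometryError):
            contact_angle_first_contact(ch, 4.0)

    def test_monotone_in_geometry(self):
        # theta grows with W_con at fixed R_con, and with R_con at fixed W_con;
        # s grows with R_con and shrinks with W_con
        thetas_w = [contact_angle_first_contact(RectChannel(H=8.2, W_con=w), 4.0)
                    for w in (3.112, 4.368, 5.7)]
        assert thetas_w == sorted(thetas_w)
        thetas_r = [contact_angle_first_contact(RectChannel(H=8.2, R_con=r), 4.0)
                    for r in (16.15, 27.525, 42.15)]
        assert thetas_r == sorted(thetas_r)
        s_r = [squeeze_length(RectChannel(H=8.2, R_con=r), 4.0).s
               for r in (16.15, 27.525, 42.15)]
        assert s_r == sorted(s_r)
        s_w = [squeeze_length(RectChannel(H=8.2, W_con=w), 4.0).s
               for w in (3.112, 4.368, 5.7)]
        assert s_w == sorted(s_w, reverse=True)
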