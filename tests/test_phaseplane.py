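"""Planar reduction, nullclines, and cross-module steady-state agreement."""

import numpy as np
import pytest

from regcycle.dynamics import find_steady_states
from regcycle.model import (
    ConnectionMask,
    SystemInputs,
    default_parameters,
    effective_parameters,
    rhs_array,
)
from regcycle.phaseplane import (
    NullclineCurve,
    intersect_nullclines,
    nullcline,
    reduce_to_plane,
)


@pytest.fixture(scope="module")
def toggle_setup():
    p = effective_parameters(default_parameters(), "toggle")
    mask = ConnectionMask.toggle()
    inputs = SystemInputs(stress=0.5, mtor_total=1.0)
    return p, mask, inputs


class TestReduction:
    def test_qss_closure_residuals_vanish(self, params, full_mask,
                                          stress_inputs, rng):
        fld = reduce_to_plane(params, full_mask, stress_inputs,
                              ("ulk1", "ampk"))
        for _ in range(12):
            u = rng.uniform(0.02, 0.95)
            a = rng.uniform(0.02, 0.95)
            x = fld.closure(u, a)
            d = rhs_array(x, stress_inputs, params, full_mask)
            assert abs(d[2]) < 1e-8 and abs(d[3]) < 1e-8

    def test_toggle_reduction_is_identity_on_its_plane(self, toggle_setup):
        """With only ULK1 and mTOR wired, closing out AMPK/REG does not
        feed back: the planar field equals the full rhs on those rows."""
        p, mask, inputs = toggle_setup
        fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
        for u, m in [(0.1, 0.8), (0.5, 0.3), (0.9, 0.05)]:
            x = fld.closure(u, m)
            d_full = rhs_array(x, inputs, p, mask)
            d_plane = fld(u, m)
            assert d_plane[0] == pytest.approx(d_full[0], abs=1e-12)
            assert d_plane[1] == pytest.approx(d_full[2], abs=1e-12)

    def test_frozen_rule_matches_jacobian_subblock(self, params, full_mask,
                                                   stress_inputs):
        """Linearizing the frozen-closure planar field reproduces the
        corresponding 2x2 sub-block of the full Jacobian."""
        from regcycle.model import jacobian

        recs = find_steady_states(params, full_mask, stress_inputs,
                                  n_starts=30, seed=0)
        assert recs
        x = recs[0].state.as_array()
        frozen = {"mtor": x[2], "reg": x[3]}
        fld = reduce_to_plane(params, full_mask, stress_inputs,
                              ("ulk1", "ampk"), off_axis_rule="frozen",
                              frozen_values=frozen)
        J = jacobian(x, stress_inputs, params, full_mask)[:2, :2]
        h = 1e-7
        J2 = np.empty((2, 2))
        for j, dv in enumerate(np.eye(2) * h):
            J2[:, j] = (fld(x[0] + dv[0], x[1] + dv[1])
                        - fld(x[0] - dv[0], x[1] - dv[1])) / (2 * h)
        assert np.allclose(J2, J, rtol=1e-5, atol=1e-7)

    def test_invalid_axis_pair(self, params, full_mask, stress_inputs):
        with pytest.raises(ValueError):
            reduce_to_plane(params, full_mask, stress_inputs,
                            ("ulk1", "ulk1"))


class TestNullclines:
    def test_reg_nullcline_matches_closed_form(self, params, full_mask,
                                               stress_inputs):
        fld = reduce_to_plane(params, full_mask, stress_inputs,
                              ("ampk", "reg"))
        curve = nullcline(fld, "reg", grid_resolution=60)
        assert len(curve) > 10
        for a, r in curve.points:
            expected = (params.k_s_reg_basal
                        + params.k_s_reg_ampk * a) / params.k_d_reg
            assert r == pytest.approx(expected, abs=1e-6)

    def test_curve_points_are_zeros_of_the_derivative(self, toggle_setup):
        p, mask, inputs = toggle_setup
        fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
        for var in ("ulk1", "mtor"):
            curve = nullcline(fld, var, grid_resolution=80)
            assert len(curve) > 0
            for x, y in curve.points:
                assert abs(fld.derivative_of(var, x, y)) < 1e-8

    def test_rapamycin_shifts_mtor_nullcline_down(self):
        """Shrinking the mTOR pool moves the mTOR balance curve to lower
        mTOR at every ULK1 value."""
        p = effective_parameters(default_parameters(), "toggle")
        mask = ConnectionMask.toggle()
        curves = {}
        for mt in (1.0, 0.1):
            inputs = SystemInputs(stress=0.0, mtor_total=mt)
            fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
            curves[mt] = nullcline(fld, "mtor", grid_resolution=60)
        # compare mtor value at matched ulk1 grid points
        pts_full = curves[1.0].points
        pts_rapa = curves[0.1].points
        for u in np.linspace(0.05, 0.95, 7):
            m_full = pts_full[np.argmin(np.abs(pts_full[:, 0] - u)), 1]
            m_rapa = pts_rapa[np.argmin(np.abs(pts_rapa[:, 0] - u)), 1]
            assert m_rapa < m_full

    def test_resolution_floor(self, toggle_setup):
        p, mask, inputs = toggle_setup
        fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
        with pytest.raises(ValueError):
            nullcline(fld, "ulk1", grid_resolution=10)


class TestIntersections:
    def test_disjoint_curves_no_crossing(self, toggle_setup):
        p, mask, inputs = toggle_setup
        fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
        a = NullclineCurve(("ulk1", "mtor"), "ulk1",
                           [np.array([[0.0, 0.1], [1.0, 0.1]])])
        b = NullclineCurve(("ulk1", "mtor"), "mtor",
                           [np.array([[0.0, 0.9], [1.0, 0.9]])])
        assert intersect_nullclines(a, b, fld) == []

    def test_axis_pair_mismatch(self, toggle_setup):
        p, mask, inputs = toggle_setup
        fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
        a = NullclineCurve(("ulk1", "mtor"), "ulk1", [])
        b = NullclineCurve(("ulk1", "ampk"), "ampk", [])
        with pytest.raises(ValueError):
            intersect_nullclines(a, b, fld)

    def test_toggle_intersections_match_newton_multistart(self,
                                                          toggle_setup):
        """Nullcline crossings and Newton multi-start find the same steady
        states (count and location within 1e-6)."""
        p, mask, inputs = toggle_setup
        fld = reduce_to_plane(p, mask, inputs, ("ulk1", "mtor"))
        cu = nullcline(fld, "ulk1", grid_resolution=120)
        cm = nullcline(fld, "mtor", grid_resolution=120)
        via_plane = intersect_nullclines(cu, cm, fld)
        via_newton = find_steady_states(p, mask, inputs, n_starts=40,
                                        seed=0)
        assert len(via_plane) == len(via_newton)
        for a, b in zip(via_plane, via_newton):
            assert np.allclose(a.state.as_array(), b.state.as_array(),
                               atol=1e-6)
            assert a.stability_label == b.stability_label
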