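"""Structure and semantics of the core ODE model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from regcycle.model import (
    EDGE_NAMES,
    PARAM_NAMES,
    ConnectionMask,
    ParameterSet,
    SystemInputs,
    SystemState,
    apply_perturbation,
    default_parameters,
    effective_parameters,
    jacobian,
    rhs,
    rhs_array,
)


def random_valid_state(rng, inputs, params):
    return np.array([
        rng.uniform(0.01, 0.99 * params.ulk1_total),
        rng.uniform(0.01, 0.99 * params.ampk_total),
        rng.uniform(0.01, 0.99 * inputs.mtor_total) if inputs.mtor_total > 0 else 0.0,
        rng.uniform(0.01, 2.0),
    ])


class TestParameterSet:
    def test_exactly_25_tunables_all_nonnegative(self, params):
        assert params.n_tunable == 25
        assert len(PARAM_NAMES) == 25
        vals = params.as_array()
        assert np.all(vals >= 0)
        for name in PARAM_NAMES:
            if name.startswith("km_"):
                assert getattr(params, name) > 0

    def test_reg_route_stronger_than_direct_ampk_route(self, params):
        assert params.k_a_ulk_reg > params.k_a_ulk_ampk

    def test_pools_default_to_one_and_are_not_tunables(self, params):
        assert params.ulk1_total == 1.0 and params.ampk_total == 1.0
        assert "ulk1_total" not in PARAM_NAMES

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            default_parameters().replace(k_d_reg=-0.1)

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            default_parameters().replace(k_nonexistent=1.0)

    def test_array_round_trip(self, params):
        again = ParameterSet.from_array(params.as_array())
        assert again == params


class TestConnectionMask:
    def test_full_wiring(self):
        m = ConnectionMask.full()
        on = {e for e in EDGE_NAMES if getattr(m, e)}
        assert on == set(EDGE_NAMES) - {"s_to_ulk1"}

    def test_toggle_wiring(self):
        m = ConnectionMask.toggle()
        on = {e for e in EDGE_NAMES if getattr(m, e)}
        assert on == {"ulk1_inh_mtor", "mtor_inh_ulk1", "s_to_ulk1"}

    def test_direct_nfb_wiring(self):
        m = ConnectionMask.direct_nfb()
        on = {e for e in EDGE_NAMES if getattr(m, e)}
        assert on == {"s_to_ampk", "ampk_to_ulk1", "ulk1_inh_ampk",
                      "ulk1_inh_mtor", "mtor_inh_ulk1"}

    def test_triangle_wiring(self):
        m = ConnectionMask.triangle()
        on = {e for e in EDGE_NAMES if getattr(m, e)}
        assert on == {"s_to_ampk", "ampk_to_ulk1", "ulk1_inh_ampk",
                      "ulk1_inh_mtor", "mtor_inh_ulk1", "ampk_inh_mtor",
                      "mtor_inh_ampk"}

    def test_unknown_variant(self):
        with pytest.raises(KeyError):
            ConnectionMask.by_name("ring")


class TestRHS:
    def test_full_pool_has_zero_activation_leg(self, params, full_mask):
        inputs = SystemInputs(stress=1.0)
        x = np.array([params.ulk1_total, 0.2, 0.5, 0.1])
        d = rhs_array(x, inputs, params, full_mask)
        # inactive pool empty -> only the inactivation leg remains
        assert d[0] < 0

    def test_reg_decoupled_when_masked(self, params):
        mask = ConnectionMask.toggle()   # all REG edges off
        inputs = SystemInputs(stress=0.3)
        for a in (0.1, 0.5, 0.9):
            x = np.array([0.3, a, 0.4, 0.2])
            dr = rhs_array(x, inputs, params, mask)[3]
            expected = params.k_s_reg_basal - params.k_d_reg * 0.2
            assert dr == pytest.approx(expected, abs=1e-14)

    def test_out_of_pool_state_rejected(self, params, full_mask):
        with pytest.raises(ValueError):
            rhs(SystemState(1.5, 0.1, 0.1, 0.1), SystemInputs(), params,
                full_mask)
        with pytest.raises(ValueError):
            rhs(SystemState(-0.2, 0.1, 0.1, 0.1), SystemInputs(), params,
                full_mask)

    @given(st.integers(0, 10_000))
    def test_mask_linearity_each_edge_contributes_one_term(self, seed):
        """rhs(full) - rhs(without edge e) is exactly e's single term."""
        rng = np.random.default_rng(seed)
        params = default_parameters()
        inputs = SystemInputs(stress=rng.uniform(0, 2))
        x = random_valid_state(rng, inputs, params)
        full = ConnectionMask(s_to_ulk1=True)   # every edge on
        base = rhs_array(x, inputs, params, full)
        target_row = {"s_to_ampk": 1, "ampk_to_ulk1": 0, "ampk_to_reg": 3,
                      "reg_to_ulk1": 0, "reg_inh_mtor": 2, "ulk1_inh_ampk": 1,
                      "ulk1_inh_mtor": 2, "mtor_inh_ulk1": 0,
                      "ampk_inh_mtor": 2, "mtor_inh_ampk": 1, "s_to_ulk1": 0}
        for edge, row in target_row.items():
            diff = base - rhs_array(x, inputs, params, full.without(edge))
            others = np.delete(diff, row)
            assert np.allclose(others, 0.0, atol=1e-15), edge

    def test_pool_conservation_is_structural(self, params, full_mask, rng):
        """Active+inactive bookkeeping: the rhs never moves mass out of a
        cycle, so trajectories stay inside [0, pool]."""
        from regcycle.dynamics import simulate

        inputs = SystemInputs(stress=0.7, mtor_total=1.0)
        x0 = random_valid_state(rng, inputs, params)
        tc = simulate(params, full_mask, inputs,
                      SystemState.from_array(x0), t_end=50.0, output_step=0.5)
        tol = 1e-7
        assert tc.states[:, 0].min() > -tol
        assert tc.states[:, 0].max() < params.ulk1_total + tol
        assert tc.states[:, 1].max() < params.ampk_total + tol
        assert tc.states[:, 2].max() < inputs.mtor_total + tol
        assert tc.states[:, 3].min() > -tol


class TestJacobian:
    @given(st.integers(0, 10_000))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        params = default_parameters()
        inputs = SystemInputs(stress=rng.uniform(0, 3),
                              mtor_total=rng.uniform(0.1, 1))
        x = random_valid_state(rng, inputs, params)
        x[2] = min(x[2], 0.95 * inputs.mtor_total)
        mask = ConnectionMask.full()
        J = jacobian(x, inputs, params, mask)
        h = 1e-7
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            col = (rhs_array(x + e, inputs, params, mask)
                   - rhs_array(x - e, inputs, params, mask)) / (2 * h)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-6)

    def test_decoupled_system_is_diagonal(self, params):
        mask = ConnectionMask(**{e: False for e in EDGE_NAMES})
        inputs = SystemInputs(stress=1.0)
        J = jacobian(np.array([0.3, 0.4, 0.5, 0.2]), inputs, params, mask)
        off = J - np.diag(np.diag(J))
        assert np.allclose(off, 0.0)

    def test_reg_self_derivative_is_minus_degradation(self, params,
                                                      full_mask, rng):
        inputs = SystemInputs(stress=0.5)
        for _ in range(5):
            x = random_valid_state(rng, inputs, params)
            J = jacobian(x, inputs, params, full_mask)
            assert J[3, 3] == pytest.approx(-params.k_d_reg)


class TestPerturbations:
    def test_reg_to_ulk1_knockout(self, params, full_mask):
        p2, m2, extra = apply_perturbation(params, full_mask, "no_reg_to_ulk1")
        assert p2.k_a_ulk_reg == 0.0
        assert extra == {}
        changed = [n for n in PARAM_NAMES
                   if getattr(p2, n) != getattr(params, n)]
        assert changed == ["k_a_ulk_reg"]
        assert params.k_a_ulk_reg > 0          # original untouched

    def test_reg_to_mtor_knockout(self, params, full_mask):
        p2, _, _ = apply_perturbation(params, full_mask, "no_reg_to_mtor")
        assert p2.k_i_mtor_reg == 0.0

    def test_rapamycin_reports_lowered_pool(self, params, full_mask):
        p2, _, extra = apply_perturbation(params, full_mask, "rapamycin",
                                          level=0.25)
        assert extra == {"mtor_total": 0.25}
        assert p2 == params

    def test_custom_identity(self, params, full_mask):
        p2, _, _ = apply_perturbation(params, full_mask, "custom")
        assert p2 == params

    def test_unknown_perturbation(self, params, full_mask):
        with pytest.raises(KeyError):
            apply_perturbation(params, full_mask, "no_such_knob")


class TestEffectiveParameters:
    def test_full_variant_is_identity(self, params):
        assert effective_parameters(params, "full") == params

    def test_reduced_variants_strengthen_surviving_conduit(self, params):
        nfb = effective_parameters(params, "direct_nfb")
        assert nfb.k_a_ulk_ampk > params.k_a_ulk_ampk
        tog = effective_parameters(params, "toggle")
        assert tog.k_a_ulk_basal > params.k_a_ulk_basal
        # inhibitory conduits are untouched (they stay masked off)
        assert nfb.k_i_mtor_reg == params.k_i_mtor_reg

    def test_unknown_variant(self, params):
        with pytest.raises(KeyError):
            effective_parameters(params, "pentagon")
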