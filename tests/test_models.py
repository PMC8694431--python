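"""Closed-form efficiency models: values, limits and validity handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cylcap import (
    BOUNDARY_LAYER_EXPONENTS,
    DimensionlessState,
    PowerLawModel,
    boundary_layer_eta,
    creeping_flow_eta,
    creeping_flow_eta_small_rp,
    creeping_shape_factor,
    empirical_eta,
    flow_regime,
    potential_flow_eta,
    power_law_eta,
)


class TestDimensionlessState:
    def test_dimensional_construction_reproduces_definitions(self):
        st_ = DimensionlessState.from_dimensional(0.04, 217e-6, 150e-6, 1e-6)
        assert st_.reynolds == pytest.approx(0.04 * 217e-6 / 1e-6)
        assert st_.size_ratio == pytest.approx(150 / 217)

    @pytest.mark.parametrize("re,rp", [(-1, 0.1), (1, -0.1)])
    def test_negative_inputs_rejected(self, re, rp):
        with pytest.raises(ValueError):
            DimensionlessState(re, rp)


class TestCreepingFlow:
    def test_small_particle_limit_value(self):
        # eta / r_p^2 -> 1/(2.002 - ln Re); at Re = 0.1 that is 1/(2.002 + ln 10)
        eta = creeping_flow_eta(DimensionlessState(0.1, 1e-4))
        assert eta / 1e-8 == pytest.approx(0.23231, rel=1e-3)

    @pytest.mark.parametrize("re", [0.01, 0.1, 1.0])
    def test_small_particle_limit_across_re(self, re):
        eta = creeping_flow_eta(DimensionlessState(re, 1e-3))
        assert eta / 1e-6 == pytest.approx(1 / (2.002 - math.log(re)), rel=1e-2)

    def test_zero_size_particle_cannot_intercept(self):
        assert creeping_flow_eta(DimensionlessState(0.1, 0.0)) == 0.0

    @pytest.mark.parametrize("re", [0.05, 0.5, 5.0])
    def test_finite_size_ratio_is_re_independent(self, re):
        # the log-Re denominator cancels in efficiency ratios at fixed Re
        num = creeping_flow_eta(DimensionlessState(re, 0.82))
        den = creeping_flow_eta(DimensionlessState(re, 0.32))
        assert num / den == pytest.approx(5.332, rel=1e-3)

    def test_shape_factor_values(self):
        assert creeping_shape_factor(0.82) == pytest.approx(0.90925, rel=1e-4)
        assert creeping_shape_factor(0.32) == pytest.approx(0.17052, rel=1e-4)

    @pytest.mark.parametrize("re", [0.0, 5.001, 10.0])
    def test_validity_ceiling_enforced(self, re):
        with pytest.raises(ValueError, match="Re"):
            creeping_flow_eta(DimensionlessState(re, 0.1))

    def test_small_rp_variant_matches_limit(self):
        st_ = DimensionlessState(0.5, 1e-5)
        full = creeping_flow_eta(st_)
        lim = creeping_flow_eta_small_rp(st_)
        assert full == pytest.approx(lim, rel=1e-4)

    def test_configurable_constant(self):
        st_ = DimensionlessState(1.0, 0.1)
        loose = creeping_flow_eta(st_, constant=2.0)
        tight = creeping_flow_eta(st_, constant=2.002)
        assert loose > tight  # smaller denominator, larger efficiency


class TestBoundaryLayer:
    def test_direct_values(self):
        assert float(boundary_layer_eta(DimensionlessState(100, 0.1))) == pytest.approx(0.1)
        assert float(boundary_layer_eta(DimensionlessState(400, 0.01))) == pytest.approx(0.002)

    def test_doubling_rp_quadruples_eta(self):
        e1 = float(boundary_layer_eta(DimensionlessState(600, 0.01)))
        e2 = float(boundary_layer_eta(DimensionlessState(600, 0.02)))
        assert e2 / e1 == pytest.approx(4.0)

    def test_out_of_validity_flags_instead_of_raising(self):
        res = boundary_layer_eta(DimensionlessState(100, 0.1))
        assert not res.in_validity and res.note
        assert boundary_layer_eta(DimensionlessState(600, 0.01)).in_validity

    def test_model_must_carry_theory_exponents(self):
        bad = PowerLawModel(1.0, 0.7, 2.0)
        with pytest.raises(ValueError):
            boundary_layer_eta(DimensionlessState(600, 0.01), bad)


class TestEmpirical:
    def test_value(self):
        assert float(empirical_eta(DimensionlessState(100, 0.02))) == pytest.approx(
            1.79e-3, rel=1e-2
        )

    def test_validity_flag(self):
        assert empirical_eta(DimensionlessState(100, 0.02)).in_validity
        assert not empirical_eta(DimensionlessState(10, 0.02)).in_validity
        assert not empirical_eta(DimensionlessState(100, 0.05)).in_validity

    def test_zero_size(self):
        assert float(empirical_eta(DimensionlessState(100, 0.0))) == 0.0


class TestPotentialFlow:
    def test_values(self):
        assert potential_flow_eta(0.0) == 0.0
        assert potential_flow_eta(0.5) == pytest.approx(0.83333, rel=1e-4)

    def test_small_rp_linearization(self):
        assert potential_flow_eta(1e-4) == pytest.approx(2e-4, rel=1e-3)


class TestFlowRegime:
    @pytest.mark.parametrize(
        "re,label",
        [
            (10, "steady-2D"),
            (47, "steady-2D"),
            (47.001, "shedding-2D"),
            (180, "shedding-2D"),
            (200, "shedding-3D-A"),
            (260, "shedding-3D-A"),
            (261, "shedding-3D-B"),
            (1000, "shedding-3D-B"),
        ],
    )
    def test_intervals_closed_on_the_left_regime(self, re, label):
        assert flow_regime(re) == label

    def test_ceiling_error_names_bound(self):
        with pytest.raises(ValueError, match="1000"):
            flow_regime(1001)


class TestPowerLawSelfConsistency:
    @given(
        u=st.floats(0.001, 0.2),
        dc=st.floats(2e-5, 2e-2),
        rp=st.floats(0.01, 1.5),
        alpha=st.floats(0.0, 1.0),
        beta=st.floats(0.5, 2.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_dimensionless_vs_dimensional_expansion(self, u, dc, rp, alpha, beta):
        """eta(Re, r_p) composed with the state equals the expanded
        k2 nu^-a U^a Dp^b Dc^(a-b) form, to machine precision."""
        nu = 1e-6
        dp = rp * dc
        model = PowerLawModel(0.3, alpha, beta)
        state = DimensionlessState.from_dimensional(u, dc, dp, nu)
        via_state = power_law_eta(model, state)
        expanded = 0.3 * nu ** (-alpha) * u**alpha * dp**beta * dc ** (alpha - beta)
        assert via_state == pytest.approx(expanded, rel=1e-12)
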