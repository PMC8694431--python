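"""Dimensional contact-rate prediction, calibration and biomass division."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cylcap import (
    CaptureScenario,
    PowerLawModel,
    approaching_flux,
    biomass_division,
    calibrate_height,
    make_powerlaw_surface,
    power_law_CR,
    predict_contact,
)
from cylcap.surface import GridSpec


@pytest.fixture(scope="module")
def delta_surface():
    """Power-law surface with the empirical exponents (delta = -0.362)."""
    return make_powerlaw_surface(0.718, 2.08, 0.224)


class TestApproachingFlux:
    def test_direct_product(self):
        sc = CaptureScenario(
            velocity=0.06,
            collector_diameter=1e-4,
            particle_diameter=2e-5,
            collector_height=0.01,
            particle_concentration=1e6,
        )
        assert approaching_flux(sc) == pytest.approx(0.06)

    def test_linear_in_concentration(self):
        base = dict(
            velocity=0.02,
            collector_diameter=2e-4,
            particle_diameter=5e-5,
            collector_height=0.005,
        )
        f1 = approaching_flux(CaptureScenario(particle_concentration=1e6, **base))
        f2 = approaching_flux(CaptureScenario(particle_concentration=2e6, **base))
        assert f2 == pytest.approx(2 * f1)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError, match="collector_height"):
            CaptureScenario(0.01, 1e-4, 1e-5, 0.0, 1e6)


class TestPredictContact:
    def test_defining_identity_cr_eta_fp(self, surrogate_surface):
        sc = CaptureScenario.from_eco(4.0, 217.0, 150.0, 0.01, 2e7)
        pred = predict_contact(sc, surrogate_surface)
        assert pred.contact_rate == pred.efficiency * pred.approaching_flux

    def test_empirical_region_value(self, delta_surface):
        # Re = 100, r_p = 0.02: eta = 0.224 * 100^0.718 * 0.02^2.08 = 1.79e-3
        sc = CaptureScenario(
            velocity=0.02,
            collector_diameter=5e-3,
            particle_diameter=1e-4,
            collector_height=0.01,
            particle_concentration=1e6,
        )
        assert sc.reynolds == pytest.approx(100.0)
        pred = predict_contact(sc, delta_surface)
        assert pred.efficiency == pytest.approx(1.79e-3, rel=1e-2)

    def test_cr_linear_in_concentration(self, surrogate_surface):
        sc1 = CaptureScenario.from_eco(4.0, 217.0, 150.0, 0.01, 1e7)
        sc2 = CaptureScenario.from_eco(4.0, 217.0, 150.0, 0.01, 3e7)
        r1 = predict_contact(sc1, surrogate_surface).contact_rate
        r2 = predict_contact(sc2, surrogate_surface).contact_rate
        assert r2 == pytest.approx(3 * r1, rel=1e-12)

    def test_out_of_coverage_raises(self, surrogate_surface):
        sc = CaptureScenario.from_eco(50.0, 30000.0, 100.0, 0.01, 1e6)  # Re = 15000
        with pytest.raises(ValueError, match="coverage"):
            predict_contact(sc, surrogate_surface)

    def test_provenance_recorded(self, surrogate_surface):
        sc = CaptureScenario.from_eco(1.0, 10000.0, 200.0, 0.01, 1e6)  # Re = 100
        pred = predict_contact(sc, surrogate_surface)
        assert pred.provenance == "empirical"

    def test_unit_conversion_invariance(self, surrogate_surface):
        si = CaptureScenario(
            velocity=0.04,
            collector_diameter=217e-6,
            particle_diameter=150e-6,
            collector_height=0.01,
            particle_concentration=2e7,
        )
        eco = CaptureScenario.from_eco(4.0, 217.0, 150.0, 0.01, 2e7)
        a = predict_contact(si, surrogate_surface).contact_rate
        b = predict_contact(eco, surrogate_surface).contact_rate
        assert a == pytest.approx(b, rel=1e-12)


class TestPowerLawCR:
    def test_degenerate_exponents_reduce_to_flux(self):
        model = PowerLawModel(1.0, 0.0, 0.0)
        sc = CaptureScenario(0.05, 1e-3, 1e-4, 0.01, 1e6)
        assert power_law_CR(model, sc) == pytest.approx(approaching_flux(sc), rel=1e-12)

    @given(
        alpha=st.floats(0.0, 1.0),
        beta=st.floats(0.5, 2.5),
        u=st.floats(0.005, 0.1),
    )
    @settings(max_examples=20, deadline=None)
    def test_velocity_exponent_is_gamma(self, alpha, beta, u):
        """Numerical log-derivative of CR w.r.t. U equals 1 + alpha."""
        model = PowerLawModel(0.3, alpha, beta)
        sc = CaptureScenario(u, 1e-3, 1e-4, 0.01, 1e6)
        sc2 = CaptureScenario(u * 1.01, 1e-3, 1e-4, 0.01, 1e6)
        slope = math.log(power_law_CR(model, sc2) / power_law_CR(model, sc)) / math.log(1.01)
        assert slope == pytest.approx(1 + alpha, rel=1e-9, abs=1e-9)

    def test_collector_exponent_is_delta(self):
        model = PowerLawModel(0.3, 0.718, 2.08)
        sc = CaptureScenario(0.02, 1e-3, 1e-4, 0.01, 1e6)
        sc2 = CaptureScenario(0.02, 1.01e-3, 1e-4, 0.01, 1e6)
        slope = math.log(power_law_CR(model, sc2) / power_law_CR(model, sc)) / math.log(1.01)
        assert slope == pytest.approx(1 + 0.718 - 2.08, abs=1e-9)

    def test_matches_surface_prediction(self, delta_surface):
        model = PowerLawModel(0.224, 0.718, 2.08)
        sc = CaptureScenario(0.02, 5e-3, 1e-4, 0.01, 1e6)
        pred = predict_contact(sc, delta_surface)
        assert power_law_CR(model, sc) == pytest.approx(pred.contact_rate, rel=1e-9)


class TestBiomassDivision:
    def test_single_collector_is_identity(self, delta_surface):
        sc = CaptureScenario.from_eco(6.0, 100.0, 25.0, 0.01, 1e6)
        res = biomass_division(sc, 1, delta_surface)
        assert res.total_ratio == pytest.approx(1.0)

    def test_power_law_ratio_matches_analytic_form(self, delta_surface):
        """On a delta0 patch the total-rate gain is n^(1 - delta0/2)."""
        sc = CaptureScenario.from_eco(2.0, 5000.0, 100.0, 0.01, 1e6)  # Re = 100
        delta0 = 1 + 0.718 - 2.08
        for n in (2, 4, 9):
            res = biomass_division(sc, n, delta_surface)
            assert res.total_ratio == pytest.approx(n ** (1 - delta0 / 2), rel=1e-6)
            assert res.per_collector_ratio == pytest.approx(n ** (-delta0 / 2), rel=1e-6)

    def test_reference_gain_for_four_collectors(self, delta_surface):
        sc = CaptureScenario.from_eco(2.0, 5000.0, 100.0, 0.01, 1e6)
        res = biomass_division(sc, 4, delta_surface)
        assert res.total_ratio == pytest.approx(5.14, rel=1e-2)

    def test_strictly_increasing_in_n_when_delta_below_two(self, surrogate_surface):
        sc = CaptureScenario.from_eco(6.0, 100.0, 25.0, 0.01, 1e6)
        ratios = [biomass_division(sc, n, surrogate_surface).total_ratio for n in (1, 2, 4, 8)]
        assert np.all(np.diff(ratios) > 0)

    def test_coverage_error_on_excessive_division(self, surrogate_surface):
        sc = CaptureScenario.from_eco(4.0, 217.0, 150.0, 0.01, 1e6)  # r_p = 0.69
        with pytest.raises(ValueError, match="coverage"):
            biomass_division(sc, 100, surrogate_surface)  # r_p -> 6.9


class TestCalibrateHeight:
    def test_round_trip_exact(self, surrogate_surface):
        from dataclasses import replace

        sc = CaptureScenario.from_eco(3.0, 70.0, 32.0, 0.01, 1e7)
        h = calibrate_height(0.5, sc, surrogate_surface)
        pred = predict_contact(replace(sc, collector_height=h), surrogate_surface)
        assert pred.contact_rate == pytest.approx(0.5, rel=1e-12)

    def test_linear_in_observation(self, surrogate_surface):
        sc = CaptureScenario.from_eco(3.0, 70.0, 32.0, 0.01, 1e7)
        h1 = calibrate_height(0.5, sc, surrogate_surface)
        h2 = calibrate_height(1.0, sc, surrogate_surface)
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    def test_zero_observation_degenerate(self, surrogate_surface):
        sc = CaptureScenario.from_eco(3.0, 70.0, 32.0, 0.01, 1e7)
        assert calibrate_height(0.0, sc, surrogate_surface) == 0.0
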