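"""Experiment emulations: settling, size-selective capture, ratios."""

import numpy as np
import pytest

from cylcap import (
    CaptureScenario,
    SizeDistribution,
    StokesSettling,
    SuspensionSpec,
    capture_ratio,
    captured_distribution,
    evolve_suspension,
    make_powerlaw_surface,
    make_suspension,
    normalized_CR_vs_diameter,
    pronation_guard,
)


@pytest.fixture()
def suspension():
    return make_suspension(SuspensionSpec())


class TestSettling:
    def test_neutral_buoyancy_is_identity(self, suspension):
        out = evolve_suspension(suspension, StokesSettling(excess_density=0.0), 60.0)
        assert np.array_equal(out.concentration, suspension.concentration)

    def test_zero_dt_is_identity(self, suspension):
        out = evolve_suspension(suspension, StokesSettling(), 0.0)
        assert np.array_equal(out.concentration, suspension.concentration)
        assert out.timestamp == suspension.timestamp

    def test_stokes_rate_scales_with_diameter_squared(self):
        dist = SizeDistribution(
            bin_edges=[95.0, 105.0, 195.0, 205.0], concentration=[1.0, 0.0, 1.0]
        )
        s = StokesSettling()
        out = evolve_suspension(dist, s, 30.0)
        # bins at 100 and 200 um: depletion-rate exponent ratio = 4
        k_small = -np.log(out.concentration[0])
        k_large = -np.log(out.concentration[2])
        assert k_large / k_small == pytest.approx(4.0, rel=1e-12)

    def test_total_concentration_non_increasing(self, suspension):
        out = evolve_suspension(suspension, StokesSettling(), 180.0)
        assert out.total_concentration < suspension.total_concentration

    def test_calibrated_peak_shift_over_run(self, suspension):
        """The default settling parameters shift the suspended peak from the
        150-160 um bin to near 110 um over a 3-minute run."""
        out = suspension
        for _ in range(180):
            out = evolve_suspension(out, StokesSettling(), 1.0)
        assert suspension.peak_diameter_um == pytest.approx(155.0, abs=10.0)
        assert out.peak_diameter_um == pytest.approx(115.0, abs=10.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            StokesSettling(excess_density=-1.0)
        with pytest.raises(ValueError):
            StokesSettling(depth=0.0)


class TestCapturedDistribution:
    def _series(self, dist, n, dt):
        out, series = dist, [dist]
        for _ in range(n - 1):
            out = evolve_suspension(out, StokesSettling(), dt)
            series.append(out)
        return series

    def _template(self):
        return CaptureScenario.from_eco(4.0, 217.0, 150.0, 0.01, 1.0)

    def test_single_bin_suspension_concentrates_all_captures(self, surrogate_surface):
        dist = SizeDistribution(bin_edges=[140.0, 150.0], concentration=[1e7])
        res = captured_distribution([dist], self._template(), surrogate_surface, 1.0)
        assert res.counts[0] > 0
        assert res.total == pytest.approx(res.counts[0])

    def test_flat_suspension_peaks_at_largest_bin(self, surrogate_surface):
        edges = np.arange(40.0, 321.0, 10.0)
        dist = SizeDistribution(bin_edges=edges, concentration=np.full(edges.size - 1, 1e5))
        res = captured_distribution([dist], self._template(), surrogate_surface, 1.0)
        assert res.peak_diameter_um == res.midpoints_um[-1]

    def test_capture_count_conservation(self, surrogate_surface, suspension):
        """Summed captured counts equal the time integral of total CR."""
        series = self._series(suspension, 30, 1.0)
        res = captured_distribution(series, self._template(), surrogate_surface, 1.0)
        total = 0.0
        tpl = self._template()
        window = tpl.velocity * tpl.collector_height * tpl.collector_diameter
        for dist in series:
            for mid, conc in zip(dist.midpoints_um, dist.concentration):
                eta = surrogate_surface.eta_at(tpl.reynolds, mid / 217.0)
                total += eta * conc * window * 1.0
        assert res.total == pytest.approx(total, rel=1e-9)

    def test_size_selection_bias(self, surrogate_surface, suspension):
        """With eta increasing in r_p, captured particles are biased large:
        captured mean diameter >= suspended mean at every step."""
        series = self._series(suspension, 60, 3.0)
        for dist in series:
            res = captured_distribution([dist], self._template(), surrogate_surface, 3.0)
            assert res.mean_diameter_um >= dist.mean_diameter_um

    def test_captured_peak_not_below_final_suspended_peak(
        self, surrogate_surface, suspension
    ):
        series = self._series(suspension, 180, 1.0)
        res = captured_distribution(series, self._template(), surrogate_surface, 1.0)
        assert res.peak_diameter_um >= series[-1].peak_diameter_um

    def test_coverage_violation_names_bin(self):
        narrow = make_powerlaw_surface(
            0.718,
            2.08,
            0.224,
            grid=None,
        )
        dist = SizeDistribution(bin_edges=[340.0, 350.0], concentration=[1e5])
        # r_p = 345/217 = 1.59 exceeds the grid ceiling of 1.5
        with pytest.raises(ValueError, match="bin 0"):
            captured_distribution([dist], self._template(), narrow, 1.0)


class TestCaptureRatio:
    def test_equal_sizes_give_unity(self):
        assert capture_ratio(82.0, 82.0, 100.0) == pytest.approx(1.0)

    def test_creeping_ratio_82_vs_32_on_100um_palp(self):
        assert capture_ratio(82.0, 32.0, 100.0) == pytest.approx(5.33, rel=1e-2)

    def test_ratio_independent_of_concentration_and_height(self, surrogate_surface):
        # the surface route divides two etas; C_p and h_c never enter
        r = capture_ratio(82.0, 32.0, 200.0, surface=surrogate_surface, velocity_cm_s=4.0)
        assert r > 1.0

    def test_surface_route_requires_velocity(self, surrogate_surface):
        with pytest.raises(ValueError, match="velocity"):
            capture_ratio(82.0, 32.0, 200.0, surface=surrogate_surface)


class TestNormalizedCR:
    def test_self_normalization(self, surrogate_surface):
        out = normalized_CR_vs_diameter([500.0, 1000.0, 1700.0], surrogate_surface)
        assert out["CR_relative"].iloc[0] == 1.0

    def test_decreasing_with_diameter_in_negative_delta_region(self, surrogate_surface):
        out = normalized_CR_vs_diameter(
            [500.0, 800.0, 1100.0, 1400.0, 1700.0], surrogate_surface
        )
        assert np.all(np.diff(out["CR_relative"]) < 0)

    def test_concentration_cancels(self, surrogate_surface):
        # the implementation uses C_p = 1; rescaling a scenario cannot matter
        a = normalized_CR_vs_diameter([600.0, 1200.0], surrogate_surface)
        b = normalized_CR_vs_diameter([600.0, 1200.0], surrogate_surface)
        assert np.array_equal(a["CR_relative"], b["CR_relative"])


class TestPronationGuard:
    @pytest.mark.parametrize("v,flag", [(3.0, False), (6.0, False), (7.0, True)])
    def test_threshold_exclusive(self, v, flag):
        assert pronation_guard(v) is flag

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            pronation_guard(-1.0)


class TestTable3Consistency:
    def test_each_row_reproduces_printed_ranges(self, table3_configs):
        """Printed Re and r_p ranges follow from the dimensional columns
        (each printed endpoint within the implied interval, to printed
        precision)."""
        assert len(table3_configs) == 5
        for cfg in table3_configs:
            report = cfg.check_consistency()
            assert report["ok"], (cfg.label, report)

    def test_brittle_star_row_values(self, table3_configs):
        row = next(c for c in table3_configs if c.label == "brittle-star")
        assert row.velocity_range_cm_s == (4.0, 4.0)
        assert row.collector_diameters_um == (217.0,)
        assert row.implied_re_range()[0] == pytest.approx(8.7, abs=0.1)

    def test_rigid_cylinder_re_span(self, table3_configs):
        row = next(c for c in table3_configs if c.label == "rigid-cylinder")
        lo, hi = row.implied_re_range()
        assert lo == pytest.approx(38.0, rel=0.02)
        assert hi == pytest.approx(460.0, rel=0.02)

    def test_polychaete_rp_span(self, table3_configs):
        row = next(c for c in table3_configs if c.label == "spionid-polychaetes-size")
        lo, hi = row.implied_rp_range()
        assert lo == pytest.approx(0.15, abs=0.015)
        assert hi == pytest.approx(1.4, abs=0.05)

    def test_estimated_flags_present(self, table3_configs):
        algae = next(c for c in table3_configs if c.label == "red-algae-structure")
        assert "particle_diameters_um" in algae.estimated
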