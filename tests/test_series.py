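import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carbonfeedback as cf
from carbonfeedback.series import AlignmentError, UnitsError


def flux(values, start_year=1850):
    values = np.asarray(values, dtype=float)
    years = np.arange(start_year, start_year + len(values))
    return cf.AnnualSeries(years, values, units="GtC_per_yr", kind="emission_flux")


def record(ff, luc=None):
    ff = flux(ff)
    luc = flux(luc) if luc is not None else ff.with_values(np.zeros(len(ff)))
    return cf.EmissionRecord(f_ff=ff, f_luc=luc)


class TestAnnualSeries:
    def test_rejects_gapped_years(self):
        with pytest.raises(AlignmentError):
            cf.AnnualSeries([1850, 1852, 1853], [1.0, 2.0, 3.0], "ppm",
                            "co2_concentration")

    def test_rejects_illegal_unit_kind_combo(self):
        with pytest.raises(UnitsError):
            cf.AnnualSeries([1850, 1851], [1.0, 2.0], "ppm", "temperature_anomaly")

    def test_window_and_value_at(self):
        s = cf.AnnualSeries(np.arange(1900, 1910), np.arange(10.0), "K",
                            "temperature_anomaly")
        assert s.value_at(1905) == 5.0
        w = s.window(1902, 1904)
        assert list(w.years) == [1902, 1903, 1904]


class TestCumulativeEmissions:
    def test_zero_fluxes_integrate_to_zero(self):
        cum = cf.cumulative_emissions(record(np.zeros(10)))
        assert np.all(cum.values == 0.0)
        assert cum.units == "GtC" and cum.kind == "cumulative_emission"

    def test_constant_flux_sums_linearly(self):
        cum = cf.cumulative_emissions(record(np.ones(10)))
        assert cum.values[0] == 1.0
        assert cum.values[-1] == 10.0

    def test_exponential_flux_matches_termwise_summation(self):
        f = cf.gen_exponential_emissions(60)
        cum = cf.cumulative_emissions(
            cf.EmissionRecord(f_ff=f, f_luc=f.with_values(np.zeros(60))))
        # oracle: explicit term-by-term partial sums
        expected = [sum(f.values[: i + 1]) for i in range(60)]
        np.testing.assert_allclose(cum.values, expected, rtol=1e-13)

    def test_linearity_in_the_flux(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(20), rng.random(20)
        cum_a = cf.cumulative_emissions(record(a)).values
        cum_b = cf.cumulative_emissions(record(b)).values
        cum_ab = cf.cumulative_emissions(record(a + b)).values
        np.testing.assert_allclose(cum_ab, cum_a + cum_b, rtol=1e-12)

    def test_year_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            cf.EmissionRecord(f_ff=flux(np.ones(5), 1850),
                              f_luc=flux(np.ones(5), 1851))


class TestCarbonUnitConversion:
    def test_one_ppm_is_2p12_gtc(self):
        s = cf.AnnualSeries([1850, 1851], [1.0, 0.0], "ppm", "co2_concentration")
        out = cf.convert_carbon_units(s, "GtC")
        assert out.values[0] == pytest.approx(2.12)
        assert out.values[1] == 0.0

    def test_630_gtc_is_297p17_ppm(self):
        s = cf.AnnualSeries([1850, 1851], [630.0, 630.0], "GtC",
                            "cumulative_emission")
        out = cf.convert_carbon_units(s, "ppm")
        assert out.values[0] == pytest.approx(297.1698, abs=1e-3)

    def test_temperature_series_rejected(self):
        s = cf.AnnualSeries([1850, 1851], [0.1, 0.2], "K", "temperature_anomaly")
        with pytest.raises(UnitsError):
            cf.convert_carbon_units(s, "GtC")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_roundtrip_is_identity(self, values):
        s = cf.AnnualSeries(np.arange(1850, 1850 + len(values)), values,
                            "ppm", "co2_concentration")
        back = cf.convert_carbon_units(cf.convert_carbon_units(s, "GtC"), "ppm")
        assert np.max(np.abs(back.values - s.values)) < 1e-6


class TestAnomalyBaseline:
    def test_constant_series_maps_to_zero(self):
        s = cf.AnnualSeries(np.arange(1900, 1950), np.full(50, 3.7), "K",
                            "temperature_anomaly")
        out = cf.anomaly_relative_to(s, 1910, 1940)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_ramp_centres_to_zero_mean(self):
        n = 30
        s = cf.AnnualSeries(np.arange(1900, 1900 + n), np.arange(float(n)),
                            "K", "temperature_anomaly")
        out = cf.anomaly_relative_to(s, 1900, 1900 + n - 1)
        assert abs(out.values.mean()) < 1e-12

    def test_noise_series_base_mean_below_1e12(self):
        rng = np.random.default_rng(3)
        s = cf.AnnualSeries(np.arange(1850, 1950), rng.normal(5, 2, 100), "K",
                            "temperature_anomaly")
        out = cf.anomaly_relative_to(s, 1880, 1910)
        assert abs(out.window(1880, 1910).values.mean()) < 1e-12

    def test_idempotent_for_same_base(self):
        rng = np.random.default_rng(4)
        s = cf.AnnualSeries(np.arange(1850, 1950), rng.normal(5, 2, 100), "K",
                            "temperature_anomaly")
        once = cf.anomaly_relative_to(s, 1880, 1910)
        twice = cf.anomaly_relative_to(once, 1880, 1910)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_base_outside_series_raises(self):
        s = cf.AnnualSeries(np.arange(1900, 1910), np.zeros(10), "K",
                            "temperature_anomaly")
        with pytest.raises(AlignmentError):
            cf.anomaly_relative_to(s, 1890, 1905)


class TestResampleToYears:
    def test_nearest_year_rule_with_interpolated_gaps(self):
        out = cf.resample_to_years([(1000.2, 1.0), (1002.9, 4.0)])
        assert list(out.years) == [1000, 1001, 1002, 1003]
        np.testing.assert_allclose(out.values, [1.0, 2.0, 3.0, 4.0])

    def test_already_annual_is_identity(self):
        pts = [(y, float(y) * 0.5) for y in range(1000, 1010)]
        out = cf.resample_to_years(pts)
        np.testing.assert_allclose(out.values, [0.5 * y for y in range(1000, 1010)])

    def test_irregular_points_on_a_line_reproduce_the_line(self):
        rng = np.random.default_rng(11)
        ts = np.sort(rng.uniform(1000, 1100, 10))
        ts = np.rint(ts) + rng.uniform(-0.4, 0.4, 10)  # avoid year collisions
        pts = [(t, 2.0 * np.rint(t)) for t in ts]
        out = cf.resample_to_years(pts)
        np.testing.assert_allclose(out.values, 2.0 * out.years, rtol=1e-12)

    def test_same_year_collisions_are_averaged(self):
        out = cf.resample_to_years([(1000.1, 1.0), (999.9, 3.0), (1001.0, 5.0)])
        assert out.values[0] == pytest.approx(2.0)


class TestSplineSmooth:
    def test_constant_series_unchanged(self):
        s = cf.AnnualSeries(np.arange(1000, 1200), np.full(200, 7.0), "ppm",
                            "co2_concentration")
        out = cf.spline_smooth(s, 30)
        np.testing.assert_allclose(out.values, 7.0, atol=1e-9)

    @staticmethod
    def _tone_response(period, cutoff, n=1200):
        t = np.arange(n, dtype=float)
        x = np.sin(2 * np.pi * t / period)
        s = cf.AnnualSeries(np.arange(1000, 1000 + n), x, "K",
                            "temperature_anomaly")
        out = cf.spline_smooth(s, cutoff)
        # amplitude via projection on the tone, central 2/3 to dodge edges
        sl = slice(n // 6, -n // 6)
        ref = x[sl]
        return float(out.values[sl] @ ref / (ref @ ref))

    def test_long_period_tone_passes(self):
        assert self._tone_response(period=300, cutoff=30) >= 0.95

    def test_cutoff_period_tone_halved(self):
        assert self._tone_response(period=30, cutoff=30) == pytest.approx(0.5, abs=0.1)

    def test_commutes_with_adding_a_constant(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 300)
        s = cf.AnnualSeries(np.arange(1000, 1300), vals, "K",
                            "temperature_anomaly")
        a = cf.spline_smooth(s.with_values(vals + 11.0), 20).values
        b = cf.spline_smooth(s, 20).values + 11.0
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_mean_preserved(self):
        rng = np.random.default_rng(6)
        s = cf.AnnualSeries(np.arange(1000, 1300), rng.normal(3, 1, 300), "K",
                            "temperature_anomaly")
        out = cf.spline_smooth(s, 30)
        assert out.values.mean() == pytest.approx(s.values.mean(), abs=1e-12)

    def test_bad_cutoff_raises(self):
        s = cf.AnnualSeries(np.arange(1000, 1050), np.zeros(50), "K",
                            "temperature_anomaly")
        with pytest.raises(ValueError):
            cf.spline_smooth(s, 1)
        with pytest.raises(ValueError):
            cf.spline_smooth(s, 50)


class TestAlignSeries:
    def test_mixed_start_years_truncate_to_overlap(self):
        a = cf.AnnualSeries(np.arange(1850, 2018), np.zeros(168), "K",
                            "temperature_anomaly")
        b = cf.AnnualSeries(np.arange(1880, 2018), np.zeros(138), "K",
                            "temperature_anomaly")
        out = cf.align_series([a, b])
        assert all(s.start_year == 1880 and s.end_year == 2017 for s in out)

    def test_identical_ranges_are_identity(self):
        a = cf.AnnualSeries(np.arange(1900, 1950), np.arange(50.0), "K",
                            "temperature_anomaly")
        out, = cf.align_series([a])
        np.testing.assert_array_equal(out.values, a.values)

    def test_nested_ranges_intersect(self):
        a = cf.AnnualSeries(np.arange(1000, 1851), np.zeros(851), "ppm",
                            "co2_concentration")
        b = cf.AnnualSeries(np.arange(1400, 1701), np.zeros(301), "ppm",
                            "co2_concentration")
        out = cf.align_series([a, b])
        assert all(s.start_year == 1400 and s.end_year == 1700 for s in out)

    def test_empty_overlap_raises(self):
        a = cf.AnnualSeries(np.arange(1000, 1100), np.zeros(100), "ppm",
                            "co2_concentration")
        b = cf.AnnualSeries(np.arange(1200, 1300), np.zeros(100), "ppm",
                            "co2_concentration")
        with pytest.raises(AlignmentError):
            cf.align_series([a, b])


class TestTableIO:
    def test_write_read_roundtrip(self, tmp_path):
        s = cf.AnnualSeries(np.arange(1850, 1900), np.linspace(0, 5, 50),
                            "ppm", "co2_concentration")
        path = tmp_path / "co2.csv"
        cf.write_series(s, path, sigma=np.full(50, 0.1))
        back = cf.read_series(path, units="ppm", kind="co2_concentration")
        np.testing.assert_allclose(back.values, s.values)
        header = path.read_text().splitlines()[0]
        assert header == "year,value,sigma"
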