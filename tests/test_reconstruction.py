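import datetime as dt

import numpy as np
import pytest
from scipy.stats import theilslopes

import budbreak as bb
from budbreak.reconstruction import ReconstructionError


def _ar1(rng, n, phi, sd):
    e = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


class TestReconstruct:
    def test_deleted_april_omits_exactly_that_year(self, true_dl_model):
        gaps = ((dt.date(1918, 4, 1), dt.date(1918, 4, 30)),)
        temps = bb.simulate_temperature(
            bb.ClimateGenParams(start_year=1908, n_years=30, gaps=gaps, rng_seed=2)
        )
        rec = bb.reconstruct(temps, 0.0, true_dl_model, range(1908, 1938))
        assert set(rec.omitted) == {1918}
        assert "missing" in rec.omitted[1918]
        assert set(rec.predicted) == set(range(1908, 1938)) - {1918}

    def test_identical_annual_cycle_gives_identical_doy(self, true_dl_model):
        temps = bb.simulate_temperature(
            bb.ClimateGenParams(start_year=1990, n_years=8, anomaly_sd_c=0.0)
        )
        rec = bb.reconstruct(temps, 0.0, true_dl_model, range(1991, 1998))
        # non-leap years all match; leap years may differ by the Feb 29 shift
        doys = {y: d for y, d in rec.predicted.items() if y % 4 != 0}
        assert len(set(doys.values())) == 1

    def test_warming_trend_gives_negative_slope(self, true_dl_model):
        temps = bb.simulate_temperature(
            bb.ClimateGenParams(
                start_year=1900, n_years=100, trend_c_per_decade=0.3, rng_seed=5
            )
        )
        rec = bb.reconstruct(temps, 0.0, true_dl_model, range(1900, 2000))
        years = sorted(rec.predicted)
        slope = theilslopes([rec.predicted[y] for y in years], years)[0]
        assert slope < 0

    def test_uniform_shift_never_delays(self, subarctic_temps, true_dl_model):
        base = bb.reconstruct(subarctic_temps, 0.0, true_dl_model, range(2000, 2010))
        warm = bb.reconstruct(subarctic_temps, 2.0, true_dl_model, range(2000, 2010))
        for y in base.predicted:
            assert warm.predicted[y] <= base.predicted[y]

    def test_deterministic(self, subarctic_temps, true_ia_model):
        a = bb.reconstruct(subarctic_temps, -1.4, true_ia_model, range(2001, 2010))
        b = bb.reconstruct(subarctic_temps, -1.4, true_ia_model, range(2001, 2010))
        assert a == b

    def test_ia_chilling_gap_omits_year(self, true_ia_model):
        gaps = ((dt.date(1990, 10, 1), dt.date(1990, 10, 15)),)
        temps = bb.simulate_temperature(
            bb.ClimateGenParams(start_year=1989, n_years=5, gaps=gaps, rng_seed=3)
        )
        rec = bb.reconstruct(temps, 0.0, true_ia_model, range(1990, 1994))
        assert 1991 in rec.omitted  # bud break of 1991 consumes autumn 1990
        assert 1990 in rec.predicted

    def test_empty_year_range_rejected(self, subarctic_temps, true_dl_model):
        with pytest.raises(ReconstructionError):
            bb.reconstruct(subarctic_temps, 0.0, true_dl_model, [])

    def test_csv_round_trip_statuses(self, tmp_path, subarctic_temps, true_dl_model):
        rec = bb.reconstruct(subarctic_temps, 0.0, true_dl_model, range(2000, 2010))
        path = tmp_path / "rec.csv"
        rec.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df.columns) == {"year", "doy", "status"}
        assert (df["status"] == "predicted").sum() == len(rec.predicted)


class TestFitTrend:
    def test_exact_line_recovered(self):
        series = {y: 150 - 0.04 * (y - 1908) for y in range(1908, 2015)}
        tr = bb.fit_trend(series, ar_order=1, horizon_years=107)
        assert tr.slope_ml == pytest.approx(-0.04, abs=1e-9)
        assert tr.slope_ols == pytest.approx(-0.04, abs=1e-9)
        assert tr.implied_change_days == pytest.approx(-4.28, abs=1e-6)

    def test_implied_change_is_slope_times_horizon(self):
        rng = np.random.default_rng(0)
        series = {1900 + i: 140 + float(v) for i, v in enumerate(rng.normal(0, 3, 60))}
        tr = bb.fit_trend(series, ar_order=1, horizon_years=107)
        assert tr.implied_change_days == tr.slope_ml * 107

    def test_slope_recovery_under_ar1_noise(self):
        rng = np.random.default_rng(1)
        slopes = []
        for rep in range(50):
            noise = _ar1(rng, 100, 0.3, 3.0)
            series = {1900 + i: 140 - 0.04 * i + noise[i] for i in range(100)}
            slopes.append(bb.fit_trend(series, ar_order=1).slope_ml)
        assert np.mean(slopes) == pytest.approx(-0.04, abs=0.015)

    def test_missing_years_tolerated(self):
        rng = np.random.default_rng(2)
        series = {1900 + i: 140 + float(rng.normal(0, 2)) for i in range(80)}
        for y in (1910, 1911, 1950):
            series.pop(y)
        tr = bb.fit_trend(series, ar_order=1)
        assert tr.n_years == 77
        assert np.isfinite(tr.slope_ml) and np.isfinite(tr.p_ml)

    def test_auto_order_selects_integer_order(self):
        rng = np.random.default_rng(3)
        noise = _ar1(rng, 120, 0.6, 3.0)
        series = {1880 + i: 150 + noise[i] for i in range(120)}
        tr = bb.fit_trend(series, ar_order="auto")
        assert tr.ar_order in (0, 1, 2)

    def test_too_short_series_rejected(self):
        series = {2000 + i: 140.0 + i for i in range(10)}
        with pytest.raises(ReconstructionError):
            bb.fit_trend(series)

    def test_accepts_reconstruction_series(self, subarctic_temps, true_dl_model):
        rec = bb.reconstruct(subarctic_temps, 0.0, true_dl_model, range(2000, 2010))
        tr = bb.fit_trend(rec, ar_order=0, min_years=5, horizon_years=10)
        assert np.isfinite(tr.slope_ols)


class TestAutocorrelationTest:
    def test_strong_positive_ar_detected(self):
        rng = np.random.default_rng(4)
        x = _ar1(rng, 100, 0.8, 1.0)
        dw, r1, p = bb.autocorrelation_test(x)
        assert r1 > 0.4 and p < 0.05 and dw < 1.5

    def test_alternating_series_strong_negative(self):
        dw, r1, p = bb.autocorrelation_test(np.tile([1.0, -1.0], 10))
        assert r1 < -0.8 and p < 0.05 and dw > 3.0

    def test_null_p_values_roughly_uniform(self):
        # under i.i.d. residuals the permutation p-value should be ~uniform:
        # check the rejection rate at alpha = 0.1 over 300 replicates
        rng = np.random.default_rng(5)
        rejections = sum(
            bb.autocorrelation_test(
                rng.normal(size=40), n_permutations=199, rng_seed=rep
            )[2]
            <= 0.1
            for rep in range(300)
        )
        assert 0.05 <= rejections / 300 <= 0.16

    def test_power_against_ar1(self):
        rng = np.random.default_rng(6)
        hits = sum(
            bb.autocorrelation_test(
                _ar1(rng, 100, 0.8, 1.0), n_permutations=199, rng_seed=rep
            )[2]
            < 0.05
            for rep in range(50)
        )
        assert hits >= 45  # >= 90 % power

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ReconstructionError):
            bb.autocorrelation_test(np.ones(20))
        with pytest.raises(ReconstructionError):
            bb.autocorrelation_test(np.arange(5.0))
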