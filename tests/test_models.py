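import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import budbreak as bb
from budbreak.models import GapError, ModelError

from .conftest import constant_series
from . import oracles


class TestForcingRate:
    def test_zero_at_and_below_freezing(self):
        assert bb.forcing_rate(-5.0) == 0.0
        assert bb.forcing_rate(0.0) == 0.0

    def test_half_asymptote_at_inflection(self):
        p = bb.ForcingParams(a=20.0, b=0.5, c=7.0, fu_crit=100.0)
        assert bb.forcing_rate(7.0, p) == pytest.approx(10.0)

    def test_default_parameters_at_30C(self):
        # frozen from a high-precision evaluation of the sigmoid
        assert bb.forcing_rate(30.0) == pytest.approx(25.376162653248198, rel=1e-12)

    @given(
        t1=st.floats(-30, 40, allow_nan=False),
        t2=st.floats(-30, 40, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_non_decreasing_in_temperature(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert bb.forcing_rate(lo) <= bb.forcing_rate(hi) + 1e-12

    def test_bounded_by_asymptote(self):
        t = np.linspace(-20, 44, 500)
        r = bb.forcing_rate(t)
        assert np.all(r >= 0) and np.all(r < bb.ForcingParams().a)

    def test_matches_scalar_oracle(self):
        p = bb.ForcingParams()
        for t in np.linspace(-10, 40, 101):
            assert bb.forcing_rate(float(t), p) == pytest.approx(
                oracles.forcing_rate_scalar(float(t), p.a, p.b, p.c)
            )


class TestChillingRate:
    @pytest.mark.parametrize("t", [-10.0, -3.4, 10.41, 15.0])
    def test_zero_outside_effective_range(self, t):
        assert bb.chilling_rate(t) == 0.0

    def test_intercept_at_zero_celsius(self):
        assert bb.chilling_rate(0.0) == pytest.approx(0.506)

    def test_peak_at_breakpoint_uses_rising_branch(self):
        assert bb.chilling_rate(3.5) == pytest.approx(0.159 * 3.5 + 0.506)

    def test_clamped_non_negative_near_lower_breakpoint(self):
        # the printed coefficients dip below zero just above -3.4 °C
        t = np.linspace(-3.39, -3.1, 50)
        assert np.all(bb.chilling_rate(t) >= 0.0)

    def test_unimodal_with_maximum_near_3_5(self):
        t = np.linspace(-3.3, 10.4, 1000)
        r = bb.chilling_rate(t)
        peak = t[np.argmax(r)]
        assert abs(peak - 3.5) < 0.05
        assert np.all(np.diff(r[t <= 3.4]) >= -1e-12)
        assert np.all(np.diff(r[t >= 3.6]) <= 1e-12)


class TestModelSpec:
    def test_kind_and_parameters_must_match(self):
        f = bb.ForcingParams()
        with pytest.raises(ModelError):
            bb.ModelSpec("IA", f, forcing_start_doy=100)
        with pytest.raises(ModelError):
            bb.ModelSpec("DL", f, chilling=bb.ChillingParams())

    def test_json_round_trip(self, true_dl_model, true_ia_model):
        for m in (true_dl_model, true_ia_model):
            assert bb.ModelSpec.from_json(m.to_json()) == m


class TestPredictBudbreak:
    def test_constant_forcing_closed_form(self):
        # constant rate r per day: break on the ceil(F/r)-th accumulation day
        p = bb.ForcingParams(a=20.0, b=0.5, c=7.0, fu_crit=95.0)
        model = bb.ModelSpec("DL", p, forcing_start_doy=91)  # April 1
        temps = constant_series(7.0)  # rate = a/2 = 10 FU/day
        pred = bb.predict_budbreak(temps, model, 2001)
        days = math.ceil(95.0 / 10.0)
        assert pred.date == dt.date(2001, 4, 1) + dt.timedelta(days=days - 1)

    def test_all_freezing_gives_no_break_and_zero_forcing(self):
        model = bb.ModelSpec("DL", bb.ForcingParams(), forcing_start_doy=60)
        pred = bb.predict_budbreak(constant_series(-2.0), model, 2001)
        assert pred.date is None and pred.doy is None
        assert pred.forcing_attained == 0.0

    def test_published_laanila_dl_at_constant_10C(self):
        model = bb.ModelSpec(
            "DL",
            bb.ForcingParams(a=19.8, b=0.73, c=6.1, fu_crit=124.2),
            forcing_start_doy=dt.date(2001, 3, 30).timetuple().tm_yday,
        )
        pred = bb.predict_budbreak(constant_series(10.0), model, 2001)
        # rate 18.715 FU/day -> 7 accumulation days from March 30
        assert pred.date == dt.date(2001, 4, 5)

    def test_zero_chilling_requirement_equals_fixed_date_model(
        self, subarctic_temps
    ):
        """With no chilling requirement the chilling model degenerates to a
        fixed-date release on its rest-start day.  The chilling window opens
        in the previous calendar year, so the equivalent fixed-date run
        carries the previous year's label.
        """
        f = bb.ForcingParams(a=25.0, b=0.3, c=10.0, fu_crit=60.0)
        rest = (1, 15)
        ia = bb.ModelSpec("IA", f, chilling=bb.ChillingParams(0.0, rest))
        dl = bb.ModelSpec(
            "DL", f, forcing_start_doy=dt.date(2001, *rest).timetuple().tm_yday
        )
        for year in range(2001, 2010):
            ia_pred = bb.predict_budbreak(subarctic_temps, ia, year)
            dl_pred = bb.predict_budbreak(subarctic_temps, dl, year - 1)
            assert ia_pred.date == dl_pred.date
            assert ia_pred.competence_date == dl_pred.competence_date

    def test_gap_in_consumed_window_names_the_date(self, true_dl_model):
        temps = constant_series(8.0)
        vals = temps.values.copy()
        gap_day = dt.date(2001, 4, 20)
        vals[(gap_day - temps.start).days] = np.nan
        gappy = bb.DailyTemperatureSeries("g", temps.start, vals)
        with pytest.raises(GapError, match="2001-04-20"):
            bb.predict_budbreak(gappy, true_dl_model, 2001)

    def test_gap_after_budbreak_is_ignored(self, true_dl_model):
        temps = constant_series(15.0)
        pred = bb.predict_budbreak(temps, true_dl_model, 2001)
        vals = temps.values.copy()
        vals[(pred.date + dt.timedelta(days=5) - temps.start).days] = np.nan
        gappy = bb.DailyTemperatureSeries("g", temps.start, vals)
        assert bb.predict_budbreak(gappy, true_dl_model, 2001).date == pred.date

    def test_warmer_series_never_later_and_lower_requirement_never_later(
        self, subarctic_temps, true_dl_model
    ):
        warmer = bb.adjust(subarctic_temps, 1.5)
        easier = bb.ModelSpec(
            "DL",
            bb.ForcingParams(
                true_dl_model.forcing.a,
                true_dl_model.forcing.b,
                true_dl_model.forcing.c,
                true_dl_model.forcing.fu_crit * 0.7,
            ),
            forcing_start_doy=true_dl_model.forcing_start_doy,
        )
        for year in range(2001, 2010):
            base = bb.predict_budbreak(subarctic_temps, true_dl_model, year).date
            assert bb.predict_budbreak(warmer, true_dl_model, year).date <= base
            assert bb.predict_budbreak(subarctic_temps, easier, year).date <= base


class TestOracleEquivalence:
    """The vectorized predictor must match an independent day-loop oracle."""

    @pytest.mark.parametrize("kind", ["DL", "IA"])
    def test_agrees_on_random_series_and_models(self, kind):
        rng = np.random.default_rng(42)
        for rep in range(30):
            temps = bb.simulate_temperature(
                bb.ClimateGenParams(
                    start_year=2000, n_years=2, rng_seed=int(rng.integers(2**31))
                )
            )
            f = bb.ForcingParams(
                a=float(rng.uniform(15, 40)),
                b=float(rng.uniform(0.05, 1.0)),
                c=float(rng.uniform(5, 15)),
                fu_crit=float(rng.uniform(20, 200)),
            )
            if kind == "DL":
                model = bb.ModelSpec(
                    "DL", f, forcing_start_doy=int(rng.integers(1, 152))
                )
            else:
                model = bb.ModelSpec(
                    "IA", f, chilling=bb.ChillingParams(float(rng.uniform(0, 120)))
                )
            expected = oracles.brute_force_predict(temps, model, 2001)
            assert bb.predict_budbreak(temps, model, 2001).date == expected


class TestAccumulationCurves:
    def test_zero_forcing_under_constant_freezing(self):
        model = bb.ModelSpec("DL", bb.ForcingParams(), forcing_start_doy=60)
        curves = bb.accumulation_curves(constant_series(0.0), model, 2001)
        assert (curves["fu_cum"] == 0.0).all()

    def test_columns_non_decreasing_and_consistent_with_prediction(
        self, subarctic_temps, true_ia_model
    ):
        curves = bb.accumulation_curves(subarctic_temps, true_ia_model, 2003)
        assert (curves["cu_cum"].diff().dropna() >= -1e-12).all()
        assert (curves["fu_cum"].diff().dropna() >= -1e-12).all()
        pred = bb.predict_budbreak(subarctic_temps, true_ia_model, 2003)
        assert curves["fu_cum"].iloc[-1] == pytest.approx(pred.forcing_attained)

    def test_chilling_frozen_after_competence(self, subarctic_temps, true_ia_model):
        pred = bb.predict_budbreak(subarctic_temps, true_ia_model, 2004)
        curves = bb.accumulation_curves(subarctic_temps, true_ia_model, 2004)
        after = curves.loc[curves.index.date > pred.competence_date, "cu_cum"]
        assert after.nunique() == 1
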