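import datetime as dt

import numpy as np
import pytest

import budbreak as bb


@pytest.fixture(scope="session")
def subarctic_temps():
    """Ten years of gap-free synthetic subarctic temperatures."""
    return bb.simulate_temperature(
        bb.ClimateGenParams(start_year=2000, n_years=10, rng_seed=7), "subarctic"
    )


@pytest.fixture(scope="session")
def true_dl_model():
    return bb.ModelSpec(
        "DL",
        bb.ForcingParams(a=25.0, b=0.3, c=10.0, fu_crit=90.0),
        forcing_start_doy=100,
    )


@pytest.fixture(scope="session")
def true_ia_model():
    return bb.ModelSpec(
        "IA",
        bb.ForcingParams(a=25.0, b=0.3, c=10.0, fu_crit=90.0),
        chilling=bb.ChillingParams(cu_crit=40.0),
    )


@pytest.fixture(scope="session")
def dl_truth(subarctic_temps, true_dl_model):
    """Noise-free observations generated directly from the true DL model."""
    obs = []
    for year in range(2001, 2010):
        pred = bb.predict_budbreak(subarctic_temps, true_dl_model, year)
        assert pred.date is not None
        obs.append(bb.BudBreakObservation("plot-1", year, pred.date))
    return obs


def constant_series(value, year=2001, site="const"):
    """One calendar year at a constant temperature."""
    start = dt.date(year, 1, 1)
    n = (dt.date(year, 12, 31) - start).days + 1
    return bb.DailyTemperatureSeries(site, start, np.full(n, float(value)))
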