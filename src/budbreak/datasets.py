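"""Published study constants: observed dates, fitted models, bounds, offsets.

These are the printed inputs of the original Scots pine bud-break study in
northern Finland — two sapling sites, Laanila (Inari, ~68.5°N) and
Vanttauskoski (Rovaniemi, ~66.4°N), each followed over several 3-year
periods between 2001 and 2013.  They serve as worked-example inputs and as
documentation constants; the underlying daily station records (Sodankylä
1908–2014, Karasjok 1877–2014) are not distributed and must be supplied or
simulated by the user.
"""

from __future__ import annotations

import datetime as dt

from .calibration import ParameterBounds
from .models import ChillingParams, ForcingParams, ModelSpec
from .observations import BudBreakObservation

#: Observed bud-break dates per plot and year (five plots, 15 plot-years).
OBSERVED_BUD_BREAK: tuple[BudBreakObservation, ...] = tuple(
    BudBreakObservation(plot, d.year, d)
    for plot, dates in [
        ("laanila-1", [dt.date(2001, 5, 17), dt.date(2002, 5, 1), dt.date(2003, 5, 13)]),
        ("laanila-2", [dt.date(2008, 5, 26), dt.date(2009, 5, 14), dt.date(2010, 5, 18)]),
        ("vanttauskoski-1", [dt.date(2001, 5, 6), dt.date(2002, 4, 30), dt.date(2003, 5, 9)]),
        ("vanttauskoski-2", [dt.date(2008, 5, 21), dt.date(2009, 5, 10), dt.date(2010, 5, 13)]),
        ("vanttauskoski-3", [dt.date(2011, 5, 11), dt.date(2012, 5, 12), dt.date(2013, 5, 14)]),
    ]
    for d in dates
)

#: Plot → site mapping for the five observation plots.
SITE_OF_PLOT: dict[str, str] = {
    "laanila-1": "laanila",
    "laanila-2": "laanila",
    "vanttauskoski-1": "vanttauskoski",
    "vanttauskoski-2": "vanttauskoski",
    "vanttauskoski-3": "vanttauskoski",
}


def observations_for_site(site: str) -> list[BudBreakObservation]:
    """All published plot-year observations belonging to one site."""
    return [o for o in OBSERVED_BUD_BREAK if SITE_OF_PLOT[o.plot_id] == site]


#: Published best-fit models per site (with their reported RMSE in days).
FITTED_MODELS: dict[tuple[str, str], tuple[ModelSpec, float]] = {
    ("laanila", "DL"): (
        ModelSpec(
            "DL",
            ForcingParams(a=19.8, b=0.73, c=6.1, fu_crit=124.2),
            forcing_start_doy=dt.date(2001, 3, 30).timetuple().tm_yday,  # March 30
        ),
        1.58,
    ),
    ("laanila", "IA"): (
        ModelSpec(
            "IA",
            ForcingParams(a=31.9, b=0.53, c=7.8, fu_crit=127.9),
            chilling=ChillingParams(cu_crit=15.4),
        ),
        1.58,
    ),
    ("vanttauskoski", "DL"): (
        ModelSpec(
            "DL",
            ForcingParams(a=21.5, b=0.47, c=6.0, fu_crit=196.2),
            forcing_start_doy=dt.date(2001, 3, 7).timetuple().tm_yday,  # March 7
        ),
        3.12,
    ),
    ("vanttauskoski", "IA"): (
        ModelSpec(
            "IA",
            ForcingParams(a=15.8, b=0.95, c=6.2, fu_crit=112.4),
            chilling=ChillingParams(cu_crit=21.7),
        ),
        3.45,
    ),
}

#: Published site-minus-station April–May offsets (°C), station + offset ≈ site.
STATION_OFFSETS_C: dict[tuple[str, str], float] = {
    ("laanila", "sodankyla"): -1.4,
    ("vanttauskoski", "sodankyla"): +0.7,
    ("laanila", "karasjok"): -0.4,
    ("vanttauskoski", "karasjok"): +1.7,
}

#: Span of the long station records used for reconstruction.
STATION_YEARS: dict[str, tuple[int, int]] = {
    "sodankyla": (1908, 2014),
    "karasjok": (1877, 2014),
}

#: Range of reported ML trend coefficients (days/year) for the Karasjok
#: reconstructions and the record length they were reported over.
ML_TREND_COEFFICIENTS = (-0.028, -0.045)
TREND_HORIZON_YEARS = 107


def published_bounds(kind: str) -> ParameterBounds:
    """The published optimization bounds for a model kind ('IA' or 'DL')."""
    return ParameterBounds.published(kind)
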