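"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's vectorized code paths: plain Python
day loops and ``math.exp``, written from the model definitions alone, so
agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import datetime as dt
import math


def forcing_rate_scalar(temp_c: float, a: float, b: float, c: float) -> float:
    if temp_c <= 0.0:
        return 0.0
    return a / (1.0 + math.exp(-b * (temp_c - c)))


def chilling_rate_scalar(temp_c: float) -> float:
    if temp_c <= -3.4 or temp_c > 10.4:
        return 0.0
    r = 0.159 * temp_c + 0.506 if temp_c <= 3.5 else -0.159 * temp_c + 1.621
    return max(r, 0.0)


def brute_force_predict(temps, model, year: int) -> dt.date | None:
    """Day-by-day accumulation loop over a daily temperature series.

    Chilling competence is checked at the end of each chilling day and
    forcing begins the following day; a zero chilling requirement (and the
    fixed-date model) force from the start day inclusive.
    """
    f = model.forcing
    end = dt.date(year, 6, 30)
    if model.kind == "DL":
        day = dt.date(year, 1, 1) + dt.timedelta(days=int(model.forcing_start_doy) - 1)
        competent = True
        cu_crit = 0.0
    else:
        m, d = model.chilling.rest_start
        day = dt.date(year - 1, m, d)
        cu_crit = model.chilling.cu_crit
        competent = cu_crit <= 0.0
    cu = 0.0
    fu = 0.0
    while day <= end:
        temp = temps.get(day)
        if temp is None:
            raise ValueError(f"gap at {day}")
        if competent:
            fu += forcing_rate_scalar(temp, f.a, f.b, f.c)
            if fu >= f.fu_crit:
                return day
        else:
            cu += chilling_rate_scalar(temp)
            if cu >= cu_crit:
                competent = True
        day += dt.timedelta(days=1)
    return None


def brute_force_budbreak_day(measurements, tree_fraction=0.5, min_tree_mm=1.0,
                             min_plot_fraction=0.01) -> dt.date | None:
    """Daily evaluation of the bud-break criteria by hand interpolation.

    For every calendar day of the measurement span, each tree's cumulative
    length is linearly interpolated between its neighbouring visits (flat
    outside its own visits) and both criteria are checked directly.
    """
    by_tree: dict[str, list] = {}
    for m in measurements:
        by_tree.setdefault(m.tree_id, []).append(m)
    for ms in by_tree.values():
        ms.sort(key=lambda m: m.date)
    dates = sorted({m.date for m in measurements})
    start, end = dates[0], dates[-1]
    totals = {t: ms[-1].cum_length_mm for t, ms in by_tree.items()}
    mean_total = sum(totals.values()) / len(totals)

    def interp(ms, day):
        if day <= ms[0].date:
            return ms[0].cum_length_mm
        if day >= ms[-1].date:
            return ms[-1].cum_length_mm
        for a, b in zip(ms, ms[1:]):
            if a.date <= day <= b.date:
                span = (b.date - a.date).days
                frac = (day - a.date).days / span
                return a.cum_length_mm + frac * (b.cum_length_mm - a.cum_length_mm)
        raise AssertionError

    day = start
    while day <= end:
        lengths = [interp(ms, day) for ms in by_tree.values()]
        frac = sum(1 for v in lengths if v >= min_tree_mm) / len(lengths)
        mean_len = sum(lengths) / len(lengths)
        if frac > tree_fraction and mean_len >= min_plot_fraction * mean_total:
            return day
        day += dt.timedelta(days=1)
    return None
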