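"""Deriving observed bud-break dates from leader-shoot growth measurements.

Field crews measure the cumulative length of each sample tree's leader
shoot roughly weekly through the growing season.  A plot is scored as having
broken bud on the earliest day on which BOTH of these hold:

* more than half of the sample trees have elongated at least 1 mm, and
* the plot-mean increment is at least 1 % of the plot-mean total height
  growth of that season.

Because the criteria are usually met between visits, each tree's cumulative
length is linearly interpolated to daily resolution first and the criteria
are then evaluated on the daily grid.  The season total of a tree is its
final cumulative measurement of the season.
"""

from __future__ import annotations

import csv
import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ObservationError(ValueError):
    """Raised for invalid growth-measurement input."""


@dataclass(frozen=True)
class GrowthMeasurement:
    """One cumulative leader-shoot length reading for one tree."""

    plot_id: str
    tree_id: str
    date: dt.date
    cum_length_mm: float

    def __post_init__(self) -> None:
        if self.cum_length_mm < 0:
            raise ObservationError(
                f"negative cumulative length for tree {self.tree_id}"
            )


@dataclass(frozen=True)
class BudBreakObservation:
    """Observed (or derived) bud-break date for one plot-year.

    ``censored`` flags plot-years whose criteria already held at the first
    measurement, so the true date may be earlier (left-censoring).
    """

    plot_id: str
    year: int
    date: dt.date
    censored: bool = False

    def __post_init__(self) -> None:
        if self.date.year != self.year:
            raise ObservationError("observation date outside its year")

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass(frozen=True)
class NoBudBreak:
    """Explicit result when the criteria are never satisfied."""

    plot_id: str
    year: int
    reason: str = "criteria never satisfied"


@dataclass(frozen=True)
class BudBreakRule:
    """Thresholds of the bud-break criterion.

    ``tree_fraction`` is the fraction of trees that must STRICTLY be
    exceeded ("more than half" → 0.5); ``min_tree_mm`` the per-tree
    elongation threshold; ``min_plot_fraction`` the plot-mean increment as a
    fraction of the plot-mean season total.
    """

    tree_fraction: float = 0.5
    min_tree_mm: float = 1.0
    min_plot_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.tree_fraction <= 1:
            raise ObservationError("tree_fraction must be in (0, 1]")
        if self.min_tree_mm <= 0 or self.min_plot_fraction <= 0:
            raise ObservationError("thresholds must be positive")


DEFAULT_RULE = BudBreakRule()


def _daily_grid(
    measurements: Sequence[GrowthMeasurement],
) -> tuple[list[dt.date], np.ndarray, np.ndarray]:
    """Interpolate each tree to the daily grid spanning all measurements.

    Returns (dates, matrix trees × days, per-tree season totals).  Trees may
    have ragged measurement dates; each is interpolated between its own
    first and last visit and held flat outside them (flat extension only
    matters when dates are ragged).
    """
    by_tree: dict[str, list[GrowthMeasurement]] = defaultdict(list)
    for m in measurements:
        by_tree[m.tree_id].append(m)
    all_dates = sorted({m.date for m in measurements})
    if len(all_dates) < 2:
        raise ObservationError("need measurements on at least two dates")
    start, end = all_dates[0], all_dates[-1]
    n_days = (end - start).days + 1
    grid_days = np.arange(n_days)
    dates = [start + dt.timedelta(days=int(i)) for i in grid_days]
    trees = sorted(by_tree)
    mat = np.empty((len(trees), n_days))
    totals = np.empty(len(trees))
    for k, tree in enumerate(trees):
        ms = sorted(by_tree[tree], key=lambda m: m.date)
        if len({m.date for m in ms}) != len(ms):
            raise ObservationError(f"duplicate measurement date for tree {tree}")
        if len(ms) < 2:
            raise ObservationError(f"tree {tree} has fewer than 2 measurements")
        x = np.array([(m.date - start).days for m in ms], dtype=float)
        y = np.array([m.cum_length_mm for m in ms])
        if np.any(np.diff(y) < 0):
            raise ObservationError(
                f"cumulative length decreases for tree {tree}"
            )
        mat[k] = np.interp(grid_days, x, y)
        totals[k] = y[-1]
    return dates, mat, totals


def derive_budbreak_date(
    measurements: Sequence[GrowthMeasurement],
    rule: BudBreakRule = DEFAULT_RULE,
) -> BudBreakObservation | NoBudBreak:
    """Apply the 1 mm / 1 % criteria to one plot-year of measurements.

    Returns a :class:`BudBreakObservation` at daily resolution — the first
    whole day on which both criteria hold on the interpolated grid — or a
    :class:`NoBudBreak` if they never do.  An observation at the first
    measurement date is flagged ``censored``.
    """
    if not measurements:
        raise ObservationError("no measurements given")
    plot_ids = {m.plot_id for m in measurements}
    years = {m.date.year for m in measurements}
    if len(plot_ids) != 1:
        raise ObservationError(f"measurements span several plots: {sorted(plot_ids)}")
    if len(years) != 1:
        raise ObservationError(f"measurements span several years: {sorted(years)}")
    plot_id, year = plot_ids.pop(), years.pop()

    dates, mat, totals = _daily_grid(measurements)
    frac_grown = np.mean(mat >= rule.min_tree_mm, axis=0)
    plot_mean = mat.mean(axis=0)
    threshold_mm = rule.min_plot_fraction * float(totals.mean())
    ok = (frac_grown > rule.tree_fraction) & (plot_mean >= threshold_mm)
    hits = np.flatnonzero(ok)
    if not hits.size:
        return NoBudBreak(plot_id, year)
    i = int(hits[0])
    return BudBreakObservation(plot_id, year, dates[i], censored=(i == 0))


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------


def read_growth_csv(path) -> list[GrowthMeasurement]:
    """Read ``plot_id,tree_id,date,cum_length_mm`` rows."""
    out: list[GrowthMeasurement] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"plot_id", "tree_id", "date", "cum_length_mm"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ObservationError(f"{path}: expected header {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    GrowthMeasurement(
                        row["plot_id"],
                        row["tree_id"],
                        dt.date.fromisoformat(row["date"]),
                        float(row["cum_length_mm"]),
                    )
                )
            except (ValueError, ObservationError) as exc:
                raise ObservationError(f"{path}:{lineno}: {exc}") from exc
    return out


def derive_all(
    measurements: Iterable[GrowthMeasurement],
    rule: BudBreakRule = DEFAULT_RULE,
) -> list[BudBreakObservation | NoBudBreak]:
    """Derive one result per (plot, year) group in the measurements."""
    groups: dict[tuple[str, int], list[GrowthMeasurement]] = defaultdict(list)
    for m in measurements:
        groups[(m.plot_id, m.date.year)].append(m)
    return [derive_budbreak_date(ms, rule) for _, ms in sorted(groups.items())]


def write_observations_csv(observations: Sequence[BudBreakObservation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plot_id", "year", "date", "doy"])
        for o in observations:
            writer.writerow([o.plot_id, o.year, o.date.isoformat(), o.doy])


def read_observations_csv(path) -> list[BudBreakObservation]:
    out: list[BudBreakObservation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                BudBreakObservation(
                    row["plot_id"], int(row["year"]), dt.date.fromisoformat(row["date"])
                )
            )
    return out


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def _month_day_position(d: dt.date) -> int:
    """Calendar position of a month-day, leap-year safe (uses a leap year
    as the common frame so Feb 29 is representable)."""
    return (dt.date(2000, d.month, d.day) - dt.date(2000, 1, 1)).days


def observation_stats(
    observations: Sequence[BudBreakObservation],
    site_of_plot: dict[str, str] | None = None,
) -> dict:
    """Per-plot and per-site spread of bud-break dates.

    Ranges compare month-day calendar positions across years, avoiding the
    leap-year off-by-one a raw DOY comparison would introduce.  Returns a
    dict with a per-plot table, the mean per-plot range, the largest range,
    and per-site mean DOY / across-year range when a plot → site mapping is
    given.
    """
    if not observations:
        raise ObservationError("no observations")
    by_plot: dict[str, list[BudBreakObservation]] = defaultdict(list)
    for o in observations:
        by_plot[o.plot_id].append(o)
    plot_rows = []
    for plot, obs in sorted(by_plot.items()):
        pos = [_month_day_position(o.date) for o in obs]
        plot_rows.append(
            {
                "plot_id": plot,
                "n_years": len(obs),
                "range_days": max(pos) - min(pos),
                "mean_doy": float(np.mean([o.doy for o in obs])),
            }
        )
    plots = pd.DataFrame(plot_rows).set_index("plot_id")
    result = {
        "plots": plots,
        "mean_plot_range_days": float(plots["range_days"].mean()),
        "largest_plot_range_days": int(plots["range_days"].max()),
    }
    if site_of_plot is not None:
        by_site: dict[str, list[BudBreakObservation]] = defaultdict(list)
        for o in observations:
            by_site[site_of_plot[o.plot_id]].append(o)
        site_rows = []
        for site, obs in sorted(by_site.items()):
            pos = [_month_day_position(o.date) for o in obs]
            site_rows.append(
                {
                    "site": site,
                    "n": len(obs),
                    "range_days": max(pos) - min(pos),
                    "mean_doy": float(np.mean([o.doy for o in obs])),
                }
            )
        result["sites"] = pd.DataFrame(site_rows).set_index("site")
    return result
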