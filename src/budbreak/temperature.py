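"""Daily and hourly air-temperature series.

Temperature is the sole driver of the bud-break models in this package, so
this module owns the container types and the handful of operations the
pipeline needs: reading and writing date/value CSV tables, aggregating
hourly logger records to daily means, deriving an additive offset between a
forest site and its reference climate station, and applying that offset.

Gaps are first-class: a daily series covers a contiguous calendar span and
every date in the span is either a recorded value or an explicit gap.  Gaps
are never interpolated here; downstream code decides what a missing day
means (for century reconstructions it means the year is omitted).
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sanity window for mean air temperature at high-latitude sites (°C).
TEMP_MIN_C = -60.0
TEMP_MAX_C = 45.0


class TemperatureError(ValueError):
    """Raised for malformed or inconsistent temperature inputs."""


def _check_temp(value: float, context: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise TemperatureError(f"non-finite temperature {value!r} ({context})")
    if not (TEMP_MIN_C <= value <= TEMP_MAX_C):
        raise TemperatureError(
            f"temperature {value} °C outside sanity window "
            f"[{TEMP_MIN_C}, {TEMP_MAX_C}] ({context})"
        )
    return value


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """Mean daily air temperature (°C) for one site over a contiguous span.

    Parameters
    ----------
    site_id:
        Free-text site label.
    start:
        First calendar date of the span (``None`` for an empty series).
    values:
        One float per day of the span; ``nan`` marks a gap.
    """

    site_id: str
    start: dt.date | None
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.size and self.start is None:
            raise TemperatureError("non-empty series requires a start date")
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < TEMP_MIN_C or finite.max() > TEMP_MAX_C):
            bad = finite[(finite < TEMP_MIN_C) | (finite > TEMP_MAX_C)][0]
            raise TemperatureError(
                f"temperature {bad} °C outside sanity window "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] in series {self.site_id!r}"
            )
        if arr.size and np.isinf(arr).any():
            raise TemperatureError("infinite temperature value")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(
        cls,
        site_id: str,
        records: Mapping[dt.date, float] | Iterable[tuple[dt.date, float | None]],
    ) -> "DailyTemperatureSeries":
        """Build a series from date → value pairs; ``None``/``nan`` = gap.

        The span runs from the earliest to the latest date given; dates in
        between that were not mentioned become gaps.  Duplicate dates raise.
        """
        if isinstance(records, Mapping):
            items = list(records.items())
        else:
            items = list(records)
        if not items:
            return cls(site_id, None, np.empty(0))
        seen: set[dt.date] = set()
        for d, _ in items:
            if d in seen:
                raise TemperatureError(f"duplicate date {d.isoformat()}")
            seen.add(d)
        start = min(d for d, _ in items)
        end = max(d for d, _ in items)
        n = (end - start).days + 1
        arr = np.full(n, np.nan)
        for d, v in items:
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                arr[(d - start).days] = _check_temp(v, d.isoformat())
        return cls(site_id, start, arr)

    # -- basic protocol --------------------------------------------------

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def end(self) -> dt.date | None:
        if self.start is None or not len(self):
            return None
        return self.start + dt.timedelta(days=len(self) - 1)

    @property
    def dates(self) -> list[dt.date]:
        if self.start is None:
            return []
        return [self.start + dt.timedelta(days=i) for i in range(len(self))]

    @property
    def gaps(self) -> set[dt.date]:
        """Dates inside the span with no recorded value."""
        if self.start is None:
            return set()
        idx = np.flatnonzero(~np.isfinite(self.values))
        return {self.start + dt.timedelta(days=int(i)) for i in idx}

    @property
    def records(self) -> dict[dt.date, float]:
        if self.start is None:
            return {}
        idx = np.flatnonzero(np.isfinite(self.values))
        return {
            self.start + dt.timedelta(days=int(i)): float(self.values[i]) for i in idx
        }

    def covers(self, d: dt.date) -> bool:
        return self.start is not None and self.start <= d <= self.end  # type: ignore[operator]

    def get(self, d: dt.date) -> float | None:
        """Value at date ``d``; ``None`` if a gap or outside the span."""
        if not self.covers(d):
            return None
        v = self.values[(d - self.start).days]  # type: ignore[operator]
        return float(v) if np.isfinite(v) else None

    def window(self, start: dt.date, end: dt.date) -> np.ndarray:
        """Values (nan = gap) for ``start..end`` inclusive.

        Raises :class:`TemperatureError` if the span does not cover the
        window.
        """
        if self.start is None or start < self.start or end > self.end:  # type: ignore[operator]
            raise TemperatureError(
                f"series {self.site_id!r} (span {self.start}..{self.end}) does not "
                f"cover window {start}..{end}"
            )
        i = (start - self.start).days
        j = (end - self.start).days + 1
        return self.values[i:j]

    def to_pandas(self) -> pd.Series:
        """The series as a pandas ``Series`` with a daily ``DatetimeIndex``."""
        if self.start is None:
            return pd.Series(dtype=float, name=self.site_id)
        idx = pd.date_range(self.start, periods=len(self), freq="D")
        return pd.Series(self.values.copy(), index=idx, name=self.site_id)


@dataclass(frozen=True)
class HourlyTemperatureSeries:
    """Sub-daily logger record: strictly increasing timestamps → °C."""

    site_id: str
    timestamps: tuple[dt.datetime, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.values):
            raise TemperatureError("timestamps and values differ in length")
        for a, b in zip(self.timestamps, self.timestamps[1:]):
            if not a < b:
                raise TemperatureError(
                    f"timestamps not strictly increasing at {b.isoformat()}"
                )
        for t, v in zip(self.timestamps, self.values):
            _check_temp(v, t.isoformat())


@dataclass(frozen=True)
class OffsetAdjustment:
    """Additive site-minus-station temperature offset (°C).

    ``station + offset ≈ site``: adding the offset to a station record puts
    it on the level of the forest site.  ``months``/``years`` record the
    window the offset was derived over.
    """

    offset_c: float
    months: frozenset[int] = frozenset()
    years: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not math.isfinite(self.offset_c):
            raise TemperatureError("offset must be finite")
        object.__setattr__(self, "months", frozenset(int(m) for m in self.months))
        object.__setattr__(self, "years", frozenset(int(y) for y in self.years))

    def to_json(self) -> str:
        return json.dumps(
            {
                "offset_c": self.offset_c,
                "months": sorted(self.months),
                "years": sorted(self.years),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OffsetAdjustment":
        d = json.loads(text)
        return cls(float(d["offset_c"]), frozenset(d["months"]), frozenset(d["years"]))


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------


def read_daily_csv(path) -> DailyTemperatureSeries:
    """Read a ``date,temp_c`` CSV into a :class:`DailyTemperatureSeries`.

    Blank ``temp_c`` cells mark gaps.  Rows out of date order are sorted with
    a warning; duplicate dates and malformed cells raise
    :class:`TemperatureError` naming the offending line.
    """
    rows: list[tuple[dt.date, float | None]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["date", "temp_c"]:
            raise TemperatureError(f"{path}: expected header 'date,temp_c'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise TemperatureError(f"{path}:{lineno}: expected 2 columns")
            try:
                d = dt.date.fromisoformat(row[0].strip())
            except ValueError as exc:
                raise TemperatureError(
                    f"{path}:{lineno}: malformed date {row[0]!r}"
                ) from exc
            cell = row[1].strip()
            if cell == "":
                rows.append((d, None))
                continue
            try:
                v = float(cell.replace("−", "-"))  # tolerate Unicode minus
            except ValueError as exc:
                raise TemperatureError(
                    f"{path}:{lineno}: non-numeric value {cell!r}"
                ) from exc
            rows.append((d, _check_temp(v, f"{path}:{lineno}")))
    dates = [d for d, _ in rows]
    if len(set(dates)) != len(dates):
        dup = next(d for i, d in enumerate(dates) if d in dates[:i])
        raise TemperatureError(f"{path}: duplicate date {dup.isoformat()}")
    if dates != sorted(dates):
        logger.warning("%s: rows out of date order; sorting", path)
        rows.sort(key=lambda r: r[0])
    site_id = str(path)
    return DailyTemperatureSeries.from_records(site_id, rows)


def write_daily_csv(series: DailyTemperatureSeries, path) -> None:
    """Write a series back to ``date,temp_c`` CSV (gaps as blank cells).

    Values are written with ``repr`` so a read/write round trip is lossless.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "temp_c"])
        for i, d in enumerate(series.dates):
            v = series.values[i]
            writer.writerow([d.isoformat(), "" if not np.isfinite(v) else repr(float(v))])


def read_hourly_csv(path) -> HourlyTemperatureSeries:
    """Read ``timestamp,temp_c`` (ISO-8601 with hour) into an hourly series."""
    stamps: list[dt.datetime] = []
    vals: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["timestamp", "temp_c"]:
            raise TemperatureError(f"{path}: expected header 'timestamp,temp_c'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t = dt.datetime.fromisoformat(row[0].strip())
            except ValueError as exc:
                raise TemperatureError(
                    f"{path}:{lineno}: malformed timestamp {row[0]!r}"
                ) from exc
            try:
                v = float(row[1])
            except (IndexError, ValueError) as exc:
                raise TemperatureError(f"{path}:{lineno}: bad value") from exc
            stamps.append(t)
            vals.append(v)
    order = sorted(range(len(stamps)), key=lambda i: stamps[i])
    if order != list(range(len(stamps))):
        logger.warning("%s: rows out of time order; sorting", path)
    return HourlyTemperatureSeries(
        str(path),
        tuple(stamps[i] for i in order),
        tuple(vals[i] for i in order),
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def aggregate_hourly_to_daily(
    hourly: HourlyTemperatureSeries, min_hours: int = 20
) -> DailyTemperatureSeries:
    """Arithmetic daily means; days with fewer than ``min_hours`` readings
    become gaps.

    The default of 20 tolerates a few dropped logger readings per day while
    refusing days whose mean would be dominated by a part of the diurnal
    cycle.
    """
    if not 1 <= min_hours <= 24:
        raise TemperatureError("min_hours must be in [1, 24]")
    by_day: dict[dt.date, list[float]] = {}
    for t, v in zip(hourly.timestamps, hourly.values):
        by_day.setdefault(t.date(), []).append(v)
    records = {
        d: (float(np.mean(vs)) if len(vs) >= min_hours else None)
        for d, vs in by_day.items()
    }
    return DailyTemperatureSeries.from_records(hourly.site_id, records)


def compute_offset(
    site: DailyTemperatureSeries,
    station: DailyTemperatureSeries,
    months: Iterable[int] = (4, 5),
    years: Iterable[int] | None = None,
) -> OffsetAdjustment:
    """Mean site − station difference over a (months × years) window.

    This is the calibration step that puts a long station record on the
    level of a forest site: the published pipeline used April–May means of
    the calibration years.  Every (month, year) cell must have at least one
    date with values on both sides, otherwise an error names the missing
    cell.  Sign convention: ``station + offset ≈ site``.
    """
    months = sorted({int(m) for m in months})
    if years is None:
        site_years = {d.year for d in site.dates}
        station_years = {d.year for d in station.dates}
        years_set = sorted(site_years & station_years)
    else:
        years_set = sorted({int(y) for y in years})
    if not months or not years_set:
        raise TemperatureError("empty offset window")
    diffs: list[float] = []
    for y in years_set:
        for m in months:
            cell: list[float] = []
            d = dt.date(y, m, 1)
            while d.month == m:
                a, b = site.get(d), station.get(d)
                if a is not None and b is not None:
                    cell.append(a - b)
                d += dt.timedelta(days=1)
            if not cell:
                raise TemperatureError(
                    f"no overlapping values for month {m}, year {y} in offset window"
                )
            diffs.extend(cell)
    return OffsetAdjustment(float(np.mean(diffs)), frozenset(months), frozenset(years_set))


def adjust(
    series: DailyTemperatureSeries, adj: OffsetAdjustment | float
) -> DailyTemperatureSeries:
    """Shift every recorded value by the offset; gaps stay gaps.

    The offset applies to all days of the year — the reconstruction scales
    whole station records, preserving their shape while moving their level.
    """
    offset = adj.offset_c if isinstance(adj, OffsetAdjustment) else float(adj)
    return DailyTemperatureSeries(series.site_id, series.start, series.values + offset)
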