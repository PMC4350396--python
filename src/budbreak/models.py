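"""Chilling/forcing bud-break models for Scots pine.

Two model structures are implemented, both sequential in the sense that
ontogenetic forcing only accumulates once the bud is competent to respond:

``IA``
    Competence develops through chilling.  Chilling units (CU) accumulate
    from a fixed rest-start date (September 1 by default) at a temperature-
    dependent rate that peaks near +3.5 °C; once the cumulative sum reaches
    ``cu_crit`` the bud is quiescent and forcing begins the following day.

``DL``
    Competence is released by a fixed calendar day-of-year (a photoperiod
    proxy); forcing accumulates from that day inclusive.

In both structures forcing units (FU) accumulate at a sigmoidal rate in
temperature — zero at or below 0 °C, saturating at ``a`` FU/day — and bud
break is predicted on the first day the cumulative sum reaches ``fu_crit``.
Accumulation is daily, driven by mean daily air temperature, with no
sub-daily interpolation.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .temperature import DailyTemperatureSeries, TemperatureError

#: Latest date considered for bud break each spring.  The latest observed
#: bud break in the calibration material is late May; June 30 leaves ample
#: margin while bounding the computation.
WINDOW_END_MONTH_DAY = (6, 30)

#: Published default forcing parameters (pooled boreal-species data).
DEFAULT_FORCING = None  # set below, after ForcingParams is defined


class ModelError(ValueError):
    """Raised for invalid model specifications or driver data."""


class GapError(ModelError):
    """A temperature gap lies inside the window the model needs to consume."""

    def __init__(self, date: dt.date, message: str | None = None):
        self.date = date
        super().__init__(message or f"temperature gap at {date.isoformat()}")


# ---------------------------------------------------------------------------
# Rate equations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForcingParams:
    """Parameters of the sigmoidal forcing-rate response.

    ``a`` is the asymptotic rate (FU/day), ``b`` the slope (1/°C), ``c`` the
    inflection temperature (°C) and ``fu_crit`` the forcing sum required for
    bud break.
    """

    a: float = 28.361
    b: float = 0.185
    c: float = 18.431
    fu_crit: float = 50.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.fu_crit >= 0):
            raise ModelError("require a > 0, b > 0, fu_crit >= 0")


DEFAULT_FORCING = ForcingParams()


@dataclass(frozen=True)
class ChillingParams:
    """Chilling requirement and the date chilling accumulation begins."""

    cu_crit: float = 20.0
    rest_start: tuple[int, int] = (9, 1)  # (month, day)

    def __post_init__(self) -> None:
        if self.cu_crit < 0:
            raise ModelError("cu_crit must be >= 0")
        m, d = self.rest_start
        dt.date(2001, m, d)  # validates month-day


def forcing_rate(temp_c, params: ForcingParams = DEFAULT_FORCING):
    """Potential forcing rate (FU/day) at air temperature ``temp_c``.

    Zero at or below 0 °C; otherwise ``a / (1 + exp(-b (T - c)))``.
    Accepts scalars or arrays.
    """
    t = np.asarray(temp_c, dtype=float)
    rate = params.a / (1.0 + np.exp(-params.b * (t - params.c)))
    out = np.where(t > 0.0, rate, 0.0)
    return float(out) if np.isscalar(temp_c) or out.ndim == 0 else out


def chilling_rate(temp_c):
    """Rate of rest-breaking chilling (CU/day) at air temperature ``temp_c``.

    Triangular response: zero at or below −3.4 °C and above 10.4 °C, rising
    as ``0.159 T + 0.506`` up to 3.5 °C and falling as ``−0.159 T + 1.621``
    above it.  The published coefficients dip marginally below zero just
    above −3.4 °C (a rounding artifact); the rate is clamped at 0 since
    chilling cannot be negative.  Accepts scalars or arrays.
    """
    t = np.asarray(temp_c, dtype=float)
    rising = 0.159 * t + 0.506
    falling = -0.159 * t + 1.621
    rate = np.where(t <= 3.5, rising, falling)
    rate = np.where((t <= -3.4) | (t > 10.4), 0.0, rate)
    rate = np.maximum(rate, 0.0)
    return float(rate) if np.isscalar(temp_c) or rate.ndim == 0 else rate


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A complete bud-break model: structure plus parameters.

    ``kind`` is ``"IA"`` (chilling-sequential) or ``"DL"`` (fixed-date
    release).  Exactly one of ``chilling`` / ``forcing_start_doy`` must be
    set, matching the kind.
    """

    kind: str
    forcing: ForcingParams
    chilling: ChillingParams | None = None
    forcing_start_doy: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("IA", "DL"):
            raise ModelError(f"unknown model kind {self.kind!r}")
        if self.kind == "IA":
            if self.chilling is None or self.forcing_start_doy is not None:
                raise ModelError("IA model requires chilling params only")
        else:
            if self.forcing_start_doy is None or self.chilling is not None:
                raise ModelError("DL model requires forcing_start_doy only")
            if not 1 <= int(self.forcing_start_doy) <= 366:
                raise ModelError("forcing_start_doy out of range")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "kind": self.kind,
            "a": self.forcing.a,
            "b": self.forcing.b,
            "c": self.forcing.c,
            "fu_crit": self.forcing.fu_crit,
        }
        if self.kind == "IA":
            assert self.chilling is not None
            d["cu_crit"] = self.chilling.cu_crit
            d["rest_start"] = "%02d-%02d" % self.chilling.rest_start
        else:
            d["forcing_start_doy"] = int(self.forcing_start_doy)  # type: ignore[arg-type]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        forcing = ForcingParams(
            float(d["a"]), float(d["b"]), float(d["c"]), float(d["fu_crit"])
        )
        if d["kind"] == "IA":
            month, day = (int(x) for x in str(d.get("rest_start", "09-01")).split("-"))
            return cls(
                "IA", forcing, chilling=ChillingParams(float(d["cu_crit"]), (month, day))
            )
        return cls("DL", forcing, forcing_start_doy=int(d["forcing_start_doy"]))

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class BudBreakPrediction:
    """Model output for one site-year."""

    year: int
    date: dt.date | None
    forcing_attained: float
    competence_date: dt.date | None

    def __post_init__(self) -> None:
        if self.date is not None and not 1 <= self.doy <= 366:
            raise ModelError("predicted DOY out of range")

    @property
    def doy(self) -> int | None:
        """Day of year of the predicted date (Jan 1 = 1), or ``None``."""
        return None if self.date is None else self.date.timetuple().tm_yday


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _window_bounds(model: ModelSpec, year: int) -> tuple[dt.date, dt.date]:
    """Calendar window the model may consume for bud break of ``year``."""
    end = dt.date(year, *WINDOW_END_MONTH_DAY)
    if model.kind == "IA":
        m, d = model.chilling.rest_start  # type: ignore[union-attr]
        return dt.date(year - 1, m, d), end
    start = dt.date(year, 1, 1) + dt.timedelta(days=int(model.forcing_start_doy) - 1)  # type: ignore[arg-type]
    return start, end


def _consume(
    temps_window: np.ndarray,
    window_start: dt.date,
    model: ModelSpec,
) -> tuple[dt.date | None, float, dt.date | None, np.ndarray, np.ndarray]:
    """Core accumulation over a gap-free window starting at the model's
    accumulation start.

    Returns (budbreak_date, forcing_attained, competence_date, cu_cum,
    fu_cum); the cumulative arrays align with the window days.  Raises
    :class:`GapError` at the first gap that would actually be consumed.
    """
    n = temps_window.size
    cu_cum = np.zeros(n)
    fu_cum = np.zeros(n)
    if model.kind == "IA":
        chl = model.chilling
        assert chl is not None
        # Competence checked after each chilling day; forcing starts the day
        # after competence.  cu_crit == 0 means competence precedes the
        # window, so forcing starts on rest_start itself.
        gap_idx = np.flatnonzero(~np.isfinite(temps_window))
        first_gap = int(gap_idx[0]) if gap_idx.size else n
        if chl.cu_crit <= 0:
            competence_idx = -1  # before the window
            competence_date = window_start
        else:
            rates = chilling_rate(np.nan_to_num(temps_window, nan=0.0))
            cum = np.cumsum(rates)
            reached = np.flatnonzero(cum >= chl.cu_crit)
            if not reached.size or reached[0] >= first_gap:
                # gap encountered while chilling still accumulating
                if first_gap < n:
                    raise GapError(window_start + dt.timedelta(days=first_gap))
                # chilling never satisfied in the whole window
                cu_cum[:] = cum
                return None, 0.0, None, cu_cum, fu_cum
            competence_idx = int(reached[0])
            competence_date = window_start + dt.timedelta(days=competence_idx)
            cu_cum[: competence_idx + 1] = cum[: competence_idx + 1]
            cu_cum[competence_idx + 1 :] = cum[competence_idx]
        forcing_from = competence_idx + 1
    else:
        competence_date = window_start
        forcing_from = 0

    sub = temps_window[forcing_from:]
    gap_idx = np.flatnonzero(~np.isfinite(sub))
    first_gap = int(gap_idx[0]) if gap_idx.size else sub.size
    rates = forcing_rate(np.nan_to_num(sub, nan=0.0), model.forcing)
    cum = np.cumsum(rates)
    reached = np.flatnonzero(cum >= model.forcing.fu_crit)
    if reached.size and reached[0] < first_gap:
        k = int(reached[0])
        fu_cum[forcing_from : forcing_from + k + 1] = cum[: k + 1]
        fu_cum[forcing_from + k + 1 :] = cum[k]
        date = window_start + dt.timedelta(days=forcing_from + k)
        return date, float(cum[k]), competence_date, cu_cum, fu_cum
    if first_gap < sub.size:
        raise GapError(window_start + dt.timedelta(days=forcing_from + first_gap))
    if sub.size:
        fu_cum[forcing_from:] = cum
        attained = float(cum[-1])
    else:
        attained = 0.0
    return None, attained, competence_date, cu_cum, fu_cum


def predict_budbreak(
    temps: DailyTemperatureSeries, model: ModelSpec, year: int
) -> BudBreakPrediction:
    """Predict the bud-break date of ``year`` from daily temperatures.

    The series must cover the model's accumulation window (for ``IA`` from
    the rest start of the previous autumn, for ``DL`` from the release day
    of ``year``) through June 30.  A gap on any day the model actually
    consumes raises :class:`GapError` naming the date; a model that does not
    reach its forcing requirement by June 30 returns a prediction with
    ``date=None``.
    """
    start, end = _window_bounds(model, year)
    window = temps.window(start, end)
    date, attained, competence, _, _ = _consume(window, start, model)
    return BudBreakPrediction(year, date, attained, competence)


def accumulation_curves(
    temps: DailyTemperatureSeries, model: ModelSpec, year: int
) -> pd.DataFrame:
    """Daily cumulative chilling and forcing for one prediction.

    Returns a DataFrame indexed by date with columns ``cu_cum`` and
    ``fu_cum``; both columns are non-decreasing and the final forcing value
    matches :func:`predict_budbreak`'s ``forcing_attained``.
    """
    start, end = _window_bounds(model, year)
    window = temps.window(start, end)
    _, _, _, cu_cum, fu_cum = _consume(window, start, model)
    idx = pd.date_range(start, end, freq="D")
    return pd.DataFrame({"cu_cum": cu_cum, "fu_cum": fu_cum}, index=idx)
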