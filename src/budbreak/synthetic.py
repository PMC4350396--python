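"""Synthetic drivers and observations with the structure the analysis assumes.

Two generators:

* :func:`simulate_temperature` produces a daily series with a sinusoidal
  high-latitude seasonal cycle, AR(1)-correlated daily anomalies, an
  optional linear warming trend and optional missing stretches — the shape
  of a subarctic station record.
* :func:`simulate_observations` produces weekly per-tree leader-shoot
  growth measurements whose underlying bud-break dates come from a known
  ("true") bud-break model, so the derivation and calibration stages can be
  exercised end to end against a known answer.

Both are pure functions of their parameter objects, including the seed.
The default climate preset is broadly plausible for the northern Finnish
study region; it is a preset for testing, not a claim about any real
station.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .models import ModelSpec, predict_budbreak
from .observations import BudBreakObservation, GrowthMeasurement
from .temperature import DailyTemperatureSeries, TEMP_MAX_C, TEMP_MIN_C


@dataclass(frozen=True)
class ClimateGenParams:
    """Parameters of the synthetic daily temperature generator.

    The daily value is

        mean + amplitude·cos(2π (doy − phase)/365.25)
             + trend·(elapsed years)/10 + AR(1) anomaly,

    where the anomaly has lag-1 coefficient ``ar1`` and marginal standard
    deviation ``anomaly_sd_c``.  ``gaps`` lists (start, end) date ranges to
    blank after generation.
    """

    start_year: int = 1908
    n_years: int = 30
    mean_c: float = -1.0
    amplitude_c: float = 14.0
    phase_doy: float = 200.0
    ar1: float = 0.6
    anomaly_sd_c: float = 3.0
    trend_c_per_decade: float = 0.0
    gaps: tuple[tuple[dt.date, dt.date], ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_c < 0 or self.anomaly_sd_c < 0:
            raise ValueError("amplitude and anomaly SD must be >= 0")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1")
        if self.n_years < 1:
            raise ValueError("need at least one year")


def simulate_temperature(p: ClimateGenParams, site_id: str = "synthetic") -> DailyTemperatureSeries:
    """Generate a gap-annotated synthetic daily temperature series."""
    start = dt.date(p.start_year, 1, 1)
    end = dt.date(p.start_year + p.n_years - 1, 12, 31)
    n = (end - start).days + 1
    days = np.arange(n)
    doy = np.array(
        [(start + dt.timedelta(days=int(i))).timetuple().tm_yday for i in days]
    )
    seasonal = p.mean_c + p.amplitude_c * np.cos(
        2 * math.pi * (doy - p.phase_doy) / 365.25
    )
    trend = p.trend_c_per_decade * (days / 365.25) / 10.0
    rng = np.random.default_rng(p.rng_seed)
    if p.anomaly_sd_c > 0:
        innov_sd = p.anomaly_sd_c * math.sqrt(1.0 - p.ar1**2)
        e = rng.normal(0.0, innov_sd, size=n)
        e[0] = rng.normal(0.0, p.anomaly_sd_c)  # stationary start
        # AR(1) recursion x[t] = ar1·x[t−1] + e[t] as an IIR filter
        anomalies = lfilter([1.0], [1.0, -p.ar1], e)
    else:
        anomalies = np.zeros(n)
    values = np.clip(seasonal + trend + anomalies, TEMP_MIN_C, TEMP_MAX_C)
    for g_start, g_end in p.gaps:
        i = max(0, (g_start - start).days)
        j = min(n - 1, (g_end - start).days)
        if i <= j:
            values[i : j + 1] = np.nan
    return DailyTemperatureSeries(site_id, start, values)


@dataclass(frozen=True)
class ObsGenParams:
    """Parameters of the synthetic growth-measurement generator.

    ``true_model`` drives the underlying bud-break date of every plot-year;
    trees within a plot start elongating with a uniform integer jitter of
    up to ``jitter_days`` days around it.  Measurements run from
    ``measurement_start`` to ``measurement_end`` (month-day) at
    ``measurement_interval``-day spacing with Gaussian length noise.
    """

    true_model: ModelSpec
    n_plots: int = 1
    n_trees: int = 10
    measurement_interval: int = 7
    noise_sd_mm: float = 0.5
    season_total_mean_mm: float = 120.0
    season_total_sd_mm: float = 30.0
    jitter_days: int = 2
    measurement_start: tuple[int, int] = (4, 20)
    measurement_end: tuple[int, int] = (8, 31)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_interval < 1:
            raise ValueError("measurement interval must be >= 1 day")
        if self.noise_sd_mm < 0 or self.season_total_sd_mm < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.jitter_days < 0:
            raise ValueError("jitter_days must be >= 0")


def _growth_curve(days_since_onset: np.ndarray, onset_mm: float, total_mm: float) -> np.ndarray:
    """Monotone rise from the onset threshold toward the season total.

    The curve jumps to ``onset_mm`` on the onset day itself (the elongation
    that defines bud break) and approaches the total with a ~40-day
    saturation scale.
    """
    rise = 1.0 - np.exp(-np.maximum(days_since_onset, 0.0) * 3.0 / 40.0)
    curve = onset_mm + (total_mm - onset_mm) * rise
    return np.where(days_since_onset >= 0, curve, 0.0)


def simulate_observations(
    temps: DailyTemperatureSeries,
    p: ObsGenParams,
    years: Sequence[int] | None = None,
    min_tree_mm: float = 1.0,
    plot_fraction: float = 0.01,
) -> tuple[list[GrowthMeasurement], list[BudBreakObservation], list[int]]:
    """Generate noisy growth measurements plus the noise-free truth.

    Returns ``(measurements, truth, skipped_years)``: for every plot-year
    the true bud-break date is the ``true_model`` prediction; years where
    the model never reaches its forcing requirement are skipped and listed.
    On the onset day each tree's cumulative length equals just above
    ``max(min_tree_mm, plot_fraction × season total)``, so with daily
    noise-free sampling the derivation criteria first hold exactly on the
    true date.
    """
    if years is None:
        assert temps.start is not None, "empty temperature series"
        first = temps.start.year + (1 if p.true_model.kind == "IA" else 0)
        years = [
            y
            for y in range(first, temps.end.year + 1)  # type: ignore[union-attr]
            if temps.covers(dt.date(y, 6, 30))
        ]
    rng = np.random.default_rng(p.rng_seed)
    measurements: list[GrowthMeasurement] = []
    truth: list[BudBreakObservation] = []
    skipped: list[int] = []
    for year in years:
        pred = predict_budbreak(temps, p.true_model, year)
        if pred.date is None:
            skipped.append(year)
            continue
        m_start = dt.date(year, *p.measurement_start)
        m_end = dt.date(year, *p.measurement_end)
        n_visits = (m_end - m_start).days // p.measurement_interval + 1
        visit_dates = [
            m_start + dt.timedelta(days=i * p.measurement_interval)
            for i in range(n_visits)
        ]
        visit_offsets = np.array([(d - pred.date).days for d in visit_dates], float)
        for plot in range(1, p.n_plots + 1):
            plot_id = f"plot-{plot}"
            truth.append(BudBreakObservation(plot_id, year, pred.date))
            totals = np.maximum(
                rng.normal(p.season_total_mean_mm, p.season_total_sd_mm, p.n_trees),
                10.0,
            )
            # +2 % headroom keeps the plot-mean criterion satisfied at onset
            onsets_mm = 1.02 * np.maximum(min_tree_mm, plot_fraction * totals)
            jitters = (
                rng.integers(-p.jitter_days, p.jitter_days + 1, p.n_trees)
                if p.jitter_days
                else np.zeros(p.n_trees, dtype=int)
            )
            for k in range(p.n_trees):
                clean = _growth_curve(
                    visit_offsets - jitters[k], float(onsets_mm[k]), float(totals[k])
                )
                noisy = clean + (
                    rng.normal(0.0, p.noise_sd_mm, clean.size)
                    if p.noise_sd_mm
                    else 0.0
                )
                # measurement noise must not break per-tree monotonicity
                noisy = np.maximum.accumulate(np.maximum(noisy, 0.0))
                for d, v in zip(visit_dates, noisy):
                    measurements.append(
                        GrowthMeasurement(plot_id, f"{plot_id}-tree-{k + 1}", d, float(v))
                    )
    return measurements, truth, skipped
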