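"""Summarize the published observation and parameter datasets.

The package ships the study's observed bud-break dates, fitted parameter
sets, station offsets and trend coefficients as constants; this script
prints their headline statistics.
"""

import budbreak as bb
from budbreak import datasets

stats = bb.observation_stats(
    list(datasets.OBSERVED_BUD_BREAK), datasets.SITE_OF_PLOT
)
print("observed bud-break dates, per-plot ranges (days):")
print(stats["plots"]["range_days"].to_string())
print(f"mean range {stats['mean_plot_range_days']:.1f} d, "
      f"largest {stats['largest_plot_range_days']} d")

print("\nfitted models (in-sample RMSE, days):")
for (site, kind), (model, rmse) in sorted(datasets.FITTED_MODELS.items()):
    print(f"  {site:14s} {kind}: F* {model.forcing.fu_crit:6.1f}, RMSE {rmse:.2f}")

print("\nstation offsets (degC):")
for pair, off in datasets.STATION_OFFSETS_C.items():
    print(f"  {pair}: {off:+.1f}")

lo, hi = (abs(c) for c in sorted(datasets.ML_TREND_COEFFICIENTS, key=abs))
h = datasets.TREND_HORIZON_YEARS
print(f"\ntrend coefficients imply a {lo * h:.1f}-{hi * h:.1f} day advance "
      f"over {h} years")
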