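"""Generate a synthetic subarctic daily-temperature record.

The generator combines a seasonal cycle, an optional warming trend and an
AR(1) anomaly; gaps can be blanked on request to mimic incomplete station
records.
"""

import datetime as dt

import numpy as np

import budbreak as bb

params = bb.ClimateGenParams(
    start_year=2000,
    n_years=3,
    trend_c_per_decade=0.0,
    gaps=((dt.date(2001, 4, 10), dt.date(2001, 4, 12)),),
    rng_seed=42,
)
temps = bb.simulate_temperature(params)

print(f"{len(temps)} days from {temps.start}")
print(f"gap days: {sorted(temps.gaps)}")
jan = [temps.get(dt.date(2001, 1, d)) for d in range(1, 32)]
jul = [temps.get(dt.date(2001, 7, d)) for d in range(1, 32)]
print(f"January 2001 mean: {np.mean(jan):6.1f} degC")
print(f"July 2001 mean:    {np.mean(jul):6.1f} degC")

# round-trip through the CSV format used by the command-line interface
bb.write_daily_csv(temps, "/tmp/demo_temps.csv")
again = bb.read_daily_csv("/tmp/demo_temps.csv")
assert np.array_equal(again.values, temps.values, equal_nan=True)
print("CSV round trip: lossless")
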