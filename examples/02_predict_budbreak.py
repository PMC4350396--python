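"""Predict bud break and inspect the chilling/forcing accumulation curves.

Compares the two model structures on the same synthetic climate: the
fixed-date model starts forcing on a calendar day, the chilling model
starts the day after its chilling requirement is met.
"""

import budbreak as bb

temps = bb.simulate_temperature(
    bb.ClimateGenParams(start_year=2000, n_years=4, rng_seed=7)
)

forcing = bb.ForcingParams(a=25.0, b=0.3, c=10.0, fu_crit=90.0)
dl = bb.ModelSpec("DL", forcing, forcing_start_doy=100)  # April 10
ia = bb.ModelSpec("IA", forcing, chilling=bb.ChillingParams(cu_crit=40.0))

for model, label in [(dl, "fixed-date"), (ia, "chilling")]:
    for year in (2002, 2003):
        p = bb.predict_budbreak(temps, model, year)
        comp = p.competence_date.isoformat() if p.competence_date else "-"
        print(
            f"{label:10s} {year}: bud break {p.date} (doy {p.doy}), "
            f"forcing attained {p.forcing_attained:6.1f} FU, "
            f"competence {comp}"
        )

curves = bb.accumulation_curves(temps, ia, 2003)
print("\nchilling-model accumulation around bud break 2003:")
print(curves.loc[str(bb.predict_budbreak(temps, ia, 2003).date)])
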