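"""Generate the default synthetic statin market and show its shape.

The default price history carries two patent expiries (simvastatin
May 2003, atorvastatin May 2012) with geometric post-expiry price decay.
Prescribers are price-sensitive, so the simvastatin initiation share rises
steeply after the first expiry and collapses after the second — the
qualitative crossover seen in the real market.
"""
import statincost as sc

SEED = 1
prices = sc.generate_price_series(sc.default_price_dynamics(), seed=SEED)
deflators = sc.synthetic_deflators(sorted({c.year for c in prices}))
records = sc.generate_cohort(sc.CohortConfig(seed=SEED), prices, deflators)

print(f"cohort: {records.patient_id.nunique():,} patients, {len(records):,} records\n")

series = sc.market_shares(records, granularity="month")
print("simvastatin initiation share:")
for label, when in [("window start", "2003-07"), ("second expiry", "2012-05"),
                    ("window end", "2018-12")]:
    print(f"  {label:>13} ({when}): {series.share('simvastatin', sc.month(when)):.2f}")

ddd_series = sc.cost_per_ddd_series(prices, deflators=deflators)
sim = ddd_series[ddd_series.statin == "simvastatin"].set_index("year").cost_per_ddd
print("\nsimvastatin cost per DDD (2018 GBP):")
for year in (2003, 2006, 2012, 2018):
    print(f"  {year}: £{sim[year]:.3f}")

print("\nThe share rises as the drug's price collapses towards the generic")
print("floor, then falls once the comparator switches to cheap atorvastatin.")
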