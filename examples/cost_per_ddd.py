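"""Standardise acquisition costs per defined daily dose (DDD).

Builds a tiny annual price table (total tablets dispensed and total net
ingredient cost per strength), pools strengths by milligram, and expresses
the result as constant-2018 GBP per DDD — the unit that makes statins of
different potency comparable.
"""
import statincost as sc

cells = [
    # year, statin, strength mg, tablets dispensed, total spend (nominal GBP)
    sc.PriceCell(2010, sc.Statin.SIMVASTATIN, 20.0, 1000.0, 40.0),
    sc.PriceCell(2010, sc.Statin.SIMVASTATIN, 40.0, 1000.0, 80.0),
    sc.PriceCell(2010, sc.Statin.ATORVASTATIN, 20.0, 1000.0, 700.0),
]
deflators = sc.DeflatorSeries({2010: 80.0, 2018: 100.0})

for statin in (sc.Statin.SIMVASTATIN, sc.Statin.ATORVASTATIN):
    nominal = sc.cost_per_ddd(statin, 2010, cells)
    real = sc.deflate(nominal, 2010, deflators)
    print(f"{statin:>13}: £{nominal:.4f}/DDD nominal -> £{real:.4f}/DDD in 2018 GBP")

print(
    "\nSimvastatin pools to £120 over 60,000 mg = £0.002/mg x 30 mg DDD;"
    "\nthe 2010 deflator index of 80 inflates both by 100/80."
)
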