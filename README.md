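# statincost

Cost-minimisation analysis of statin prescribing in English primary care.

Statins are the most widely prescribed drugs for cardiovascular prevention,
and national guidance treats the five agents in the class (simvastatin,
atorvastatin, rosuvastatin, pravastatin, fluvastatin) as therapeutically
interchangeable at doses of similar LDL-cholesterol-lowering intensity.
Because patents expired at different times (simvastatin in May 2003,
atorvastatin in May 2012), the cost-effective choice changed over time while
clinical effect did not. This package quantifies what that means in money:
it costs every prescription as issued, re-costs it as if the cost-effective
comparator had been prescribed at an equivalent dose, and reports the
difference. It is written for health economists and pharmacoepidemiologists
working with prescription-event and price/quantity data.

## What it computes

**DDD-standardised costs.** From annual price tables (total dispensed
quantity and net ingredient cost per drug strength), the average acquisition
cost per tablet is spend/quantity, and the cost per WHO defined daily dose
pools strengths by milligram:

```
cost_per_DDD(s, y) = DDD_mg(s) · Σ spend(s, m, y) / Σ quantity(s, m, y) · m
```

All money is deflated to constant 2018 GBP with a GDP-deflator series
(`amount · 100 / index(year)`).

**Dose-equivalence substitution.** Each (statin, dose) maps to a % LDL
reduction and hence an intensity band — low [20, 30], medium (30, 40],
high (> 40). A record is substituted by the smallest comparator dose in the
same band (comparator = simvastatin before May 2012, atorvastatin from May
2012 onwards), keeping tablet count and duration.

**Counterfactual savings.** Scenario 1 caps each new patient's first
prescription episode at 28 days; scenario 2 covers all prescription-days of
all patients (an upper bound). Per year and cumulatively:
`savings = actual − hypothetical`, absolute and as % of actual spend.

**Trends and heterogeneity.** Initiation market shares per month/quarter;
practice quintile series (re-ranked each period, or frozen at a baseline
quarter to expose persistence); switch-away rates after switches to a target
statin.

**Synthetic data.** A seeded generator of price series (geometric
post-expiry decay to a generic floor) and prescription cohorts (practice
preferences ~ N(0, σ²), multinomial-logit initial choice driven by price per
DDD and guideline recommendation, geometric persistence, monthly switching
to the comparator), so the full pipeline is testable without the
proprietary source extracts.

## Worked example

`python examples/savings_simulation.py` generates the default synthetic
study (15,078 patients, 337,574 records at 1/1000 of national volume) and
prints the two-panel savings table; its cumulative row reads:

```
 Total |     15,078      59,635.62      59,508.27       127.35   0.2 |     15,078   1,030,373.32     916,855.35   113,517.97  11.0
```

i.e. capping at the first 28 days of new patients' treatment the
counterfactual saves £127 (0.2% of £59.6k), while switching every
prescription-day of every patient would have saved £113.5k (11.0% of
£1.03M), all in constant 2018 GBP at desk scale. Early years show negative
savings — before generic entry the comparator was not yet the cheapest
option, and the accounting reports that honestly.

`python examples/synthetic_market.py` shows the qualitative market shape the
generator reproduces: the simvastatin initiation share rises from 0.26 at
the window start to 1.00 at the second patent expiry and falls back to 0.27
by 2018, while its cost per DDD collapses from £0.63 to £0.04.

The other examples (`cost_per_ddd.py`, `dose_substitution.py`,
`heterogeneity_quintiles.py`) each demonstrate one stage in isolation.

A thin CLI wraps the same pipeline: `statincost all --seed 1 --out results/`
writes share, quintile, cost-per-DDD and savings CSVs plus a manifest of
content hashes; `statincost simulate-data` emits the synthetic inputs as
CSV.

## Layout

- `src/statincost/domain.py` — core types (records, price cells, DDD,
  deflators, comparator policy)
- `src/statincost/io.py` — CSV readers/writers with row-level validation
- `src/statincost/pricing.py` — unit costs, cost per DDD, deflation
- `src/statincost/equivalence.py` — intensity bands and dose substitution
- `src/statincost/trends.py` — shares, quintiles, switch-away rates
- `src/statincost/simulation.py` — the two savings scenarios
- `src/statincost/synthetic.py` — price and cohort generators, choice-model
  refit
- `src/statincost/pipeline.py`, `cli.py` — config-driven pipeline and CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
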