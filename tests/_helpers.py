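"""Shared fixture builders for the test suite."""
from __future__ import annotations

import numpy as np

import statincost as sc


def make_rec(
    patient="p1",
    practice="gp1",
    month="2010-01",
    statin="simvastatin",
    strength=20.0,
    tablets=28,
    days=28,
    first=True,
):
    return sc.PrescriptionRecord(
        patient_id=patient,
        practice_id=practice,
        issue_month=month,
        statin=statin,
        strength_mg=strength,
        tablets=tablets,
        days_supplied=days,
        first_episode=first,
    )


def flat_deflators(years=range(2003, 2019)):
    return sc.DeflatorSeries({y: 100.0 for y in years})


def price_cells_for_table(table: sc.EquivalenceTable, years, rng=None, spend_per_tablet=None):
    """One price cell per (statin, catalogued dose, year).

    Unit costs are random (reproducible via ``rng``) unless a fixed
    ``spend_per_tablet`` mapping/scalar is given.
    """
    cells = []
    for statin in sc.Statin:
        for dose in table.doses(statin):
            for year in years:
                qty = 1000.0
                if spend_per_tablet is not None:
                    if isinstance(spend_per_tablet, dict):
                        uc = spend_per_tablet[(str(statin), float(dose))]
                    else:
                        uc = float(spend_per_tablet)
                else:
                    uc = float(rng.uniform(0.02, 2.0))
                cells.append(sc.PriceCell(year, statin, float(dose), qty, uc * qty))
    return cells


def random_small_fixture(rng: np.random.Generator, max_records=20, years=(2010, 2014)):
    """A random record set plus covering prices and deflators.

    Strengths are drawn from the shipped equivalence-table doses so every
    substitution target is priced. Months straddle the comparator cutover.
    """
    table = sc.EquivalenceTable.default()
    year_range = list(range(years[0], years[1] + 1))
    cells = price_cells_for_table(table, year_range, rng)
    deflators = sc.DeflatorSeries(
        {**{y: float(rng.uniform(60, 140)) for y in year_range}, 2018: 100.0}
    )
    n = int(rng.integers(1, max_records + 1))
    statins = list(sc.Statin)
    records = []
    first_flagged = set()
    for i in range(n):
        pid = f"pt{int(rng.integers(0, max(2, n // 2)))}"
        statin = statins[int(rng.integers(0, len(statins)))]
        dose = float(rng.choice(table.doses(statin)))
        first = bool(rng.random() < 0.5) and pid not in first_flagged
        if first:
            first_flagged.add(pid)
        records.append(
            make_rec(
                patient=pid,
                practice=f"gp{int(rng.integers(0, 3))}",
                month=f"{int(rng.integers(years[0], years[1] + 1))}-{int(rng.integers(1, 13)):02d}",
                statin=statin,
                strength=dose,
                tablets=int(rng.integers(1, 120)),
                days=int(rng.integers(1, 90)),
                first=first,
            )
        )
    return records, cells, table, deflators


def eq_rows(table: sc.EquivalenceTable) -> dict:
    """Plain {(statin_str, dose): pct} view for the brute-force oracle."""
    return {(str(s), float(d)): float(p) for (s, d), p in table.reductions.items()}
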