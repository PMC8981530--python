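"""Acquisition-cost computation.

The average acquisition cost per tablet of a strength-year is total NIC
spend divided by total dispensed quantity. Costs are made comparable
across drugs by expressing them per WHO defined daily dose (DDD), pooling
all strengths of a drug-year by total milligrams:

    cost_per_DDD = DDD_mg * (sum spend) / (sum quantity * strength_mg)

Money is converted to constant 2018 GBP with a GDP-deflator series
(``amount * 100 / index(year)``); deflation applies to money only, never
to quantities, and missing years are an error rather than an extrapolation.
"""
from __future__ import annotations

from typing import Iterable

import pandas as pd

from .domain import BASE_YEAR, DddTable, DeflatorSeries, PriceCell, Statin
from .errors import DuplicateKeyError, MissingDataError
from .errors import MissingDeflatorError  # re-exported for callers  # noqa: F401

__all__ = [
    "unit_cost",
    "unit_cost_index",
    "cost_per_ddd",
    "cost_per_ddd_series",
    "deflate",
]


def unit_cost(cell: PriceCell) -> float:
    """Average acquisition cost per tablet: spend / quantity (nominal GBP)."""
    return cell.total_spend / cell.total_quantity


def unit_cost_index(cells: Iterable[PriceCell]) -> dict[tuple[Statin, float, int], float]:
    """Map (statin, strength_mg, year) -> nominal GBP per tablet.

    Enforces uniqueness of the (year, statin, strength) key.
    """
    out: dict[tuple[Statin, float, int], float] = {}
    for cell in cells:
        key = (cell.statin, cell.strength_mg, cell.year)
        if key in out:
            raise DuplicateKeyError(f"duplicate price cell for {key}")
        out[key] = unit_cost(cell)
    return out


def cost_per_ddd(
    statin: Statin,
    year: int,
    cells: Iterable[PriceCell],
    ddd: DddTable | None = None,
) -> float:
    """Nominal GBP per DDD for a drug-year, pooled over strengths by milligram."""
    ddd = ddd or DddTable.default()
    statin = Statin.parse(statin)
    year = int(year)
    spend = 0.0
    mg = 0.0
    found = False
    for cell in cells:
        if cell.statin == statin and cell.year == year:
            found = True
            spend += cell.total_spend
            mg += cell.total_quantity * cell.strength_mg
    if not found:
        raise MissingDataError(f"no price cells for {statin} in {year}")
    return ddd[statin] * spend / mg


def deflate(amount: float, year: int, deflators: DeflatorSeries) -> float:
    """Nominal GBP of ``year`` -> constant 2018 GBP."""
    return amount * deflators.factor_to_base(year)


def cost_per_ddd_series(
    cells: Iterable[PriceCell],
    ddd: DddTable | None = None,
    deflators: DeflatorSeries | None = None,
) -> pd.DataFrame:
    """Tidy (year, statin, cost_per_ddd) series over all drug-years present.

    With a deflator series the costs are in constant 2018 GBP, otherwise
    nominal.
    """
    cells = list(cells)
    pairs = sorted({(c.year, c.statin) for c in cells}, key=lambda p: (p[0], str(p[1])))
    rows = []
    for year, statin in pairs:
        value = cost_per_ddd(statin, year, cells, ddd)
        if deflators is not None:
            value = deflate(value, year, deflators)
        rows.append({"year": year, "statin": str(statin), "cost_per_ddd": value})
    return pd.DataFrame(rows, columns=["year", "statin", "cost_per_ddd"])
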