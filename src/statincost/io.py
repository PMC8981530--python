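"""Delimited-text readers and writers for the five input table kinds
(prescriptions, prices, DDDs, deflators, equivalence) and the savings table.

All files are UTF-8 comma-separated with a header row; months are ISO
``YYYY-MM`` strings. Readers validate every row against the domain
invariants and report 1-based data-row numbers on failure. Writing then
reading any table reproduces it exactly.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain import (
    DEFAULT_STRENGTHS_MG,
    DddTable,
    DeflatorSeries,
    PrescriptionRecord,
    PriceCell,
    Statin,
    month,
)
from .equivalence import EquivalenceTable
from .errors import DuplicateKeyError, RowValidationError, SchemaError, StatinCostError

__all__ = [
    "read_prescriptions",
    "write_prescriptions",
    "read_prices",
    "write_prices",
    "read_ddd_table",
    "write_ddd_table",
    "read_deflators",
    "write_deflators",
    "read_equivalence",
    "write_equivalence",
    "write_savings_table",
    "read_savings_table",
]

PRESCRIPTION_COLUMNS = [
    "patient_id",
    "practice_id",
    "issue_month",
    "statin",
    "strength_mg",
    "tablets",
    "days_supplied",
    "first_episode",
]
PRICE_COLUMNS = ["year", "statin", "strength_mg", "total_quantity", "total_spend_gbp"]
SAVINGS_COLUMNS = [
    "year",
    "n_patients",
    "actual_cost",
    "hypothetical_cost",
    "savings_abs",
    "savings_pct",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _load(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise StatinCostError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _parse_bool(value: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise RowValidationError(row, f"invalid boolean {value!r} for first_episode")


def read_prescriptions(
    path, strength_catalogue: Mapping[Statin, Sequence[float]] | None = None
) -> list[PrescriptionRecord]:
    """Read prescription events, validating each row.

    ``strength_catalogue`` maps each statin to its admissible tablet
    strengths (defaults to the shipped catalogue). Rows with unknown
    statins, off-catalogue strengths, or a second first-episode flag for
    the same patient raise :class:`RowValidationError` with the 1-based
    data-row index.
    """
    catalogue = {
        Statin.parse(s): {float(v) for v in vals}
        for s, vals in (strength_catalogue or DEFAULT_STRENGTHS_MG).items()
    }
    frame = _load(path, PRESCRIPTION_COLUMNS)
    records: list[PrescriptionRecord] = []
    first_seen: dict[str, int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            statin = Statin.parse(row.statin)
            rec = PrescriptionRecord(
                patient_id=str(row.patient_id),
                practice_id=str(row.practice_id),
                issue_month=month(row.issue_month),
                statin=statin,
                strength_mg=float(row.strength_mg),
                tablets=int(row.tablets),
                days_supplied=int(row.days_supplied),
                first_episode=_parse_bool(row.first_episode, i),
            )
        except RowValidationError:
            raise
        except (StatinCostError, ValueError) as exc:
            raise RowValidationError(i, str(exc)) from None
        if statin in catalogue and rec.strength_mg not in catalogue[statin]:
            raise RowValidationError(
                i, f"strength {rec.strength_mg} mg not in catalogue for {statin}"
            )
        if statin not in catalogue:
            raise RowValidationError(i, f"statin {statin} absent from strength catalogue")
        if rec.first_episode:
            if rec.patient_id in first_seen:
                raise RowValidationError(
                    i,
                    f"patient {rec.patient_id} has a second first_episode record "
                    f"(first at row {first_seen[rec.patient_id]})",
                )
            first_seen[rec.patient_id] = i
        records.append(rec)
    return records


def write_prescriptions(records: Iterable[PrescriptionRecord] | pd.DataFrame, path) -> None:
    from .domain import records_to_frame

    frame = records_to_frame(records).copy()
    frame["issue_month"] = frame["issue_month"].astype(str)
    frame["first_episode"] = frame["first_episode"].map(lambda b: "true" if b else "false")
    frame.to_csv(path, index=False, columns=PRESCRIPTION_COLUMNS)


def read_prices(path) -> list[PriceCell]:
    """Read annual price/quantity cells; (year, statin, strength) must be unique."""
    frame = _load(path, PRICE_COLUMNS)
    cells: list[PriceCell] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            cell = PriceCell(
                year=int(row.year),
                statin=Statin.parse(row.statin),
                strength_mg=float(row.strength_mg),
                total_quantity=float(row.total_quantity),
                total_spend=float(row.total_spend_gbp),
            )
        except (StatinCostError, ValueError) as exc:
            raise RowValidationError(i, str(exc)) from None
        if cell.key in seen:
            raise DuplicateKeyError(
                f"duplicate price cell {cell.key} at rows {seen[cell.key]} and {i}"
            )
        seen[cell.key] = i
        cells.append(cell)
    return cells


def write_prices(cells: Iterable[PriceCell], path) -> None:
    rows = list(cells)
    pd.DataFrame(
        {
            "year": [c.year for c in rows],
            "statin": [str(c.statin) for c in rows],
            "strength_mg": [c.strength_mg for c in rows],
            "total_quantity": [c.total_quantity for c in rows],
            "total_spend_gbp": [c.total_spend for c in rows],
        }
    ).to_csv(path, index=False)


def read_ddd_table(path) -> DddTable:
    frame = _load(path, ["statin", "ddd_mg"])
    mapping = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            mapping[Statin.parse(row.statin)] = float(row.ddd_mg)
        except (StatinCostError, ValueError) as exc:
            raise RowValidationError(i, str(exc)) from None
    return DddTable(mapping)


def write_ddd_table(table: DddTable, path) -> None:
    items = sorted(table.ddd_mg.items(), key=lambda kv: str(kv[0]))
    pd.DataFrame(
        {"statin": [str(s) for s, _ in items], "ddd_mg": [v for _, v in items]}
    ).to_csv(path, index=False)


def read_deflators(path) -> DeflatorSeries:
    frame = _load(path, ["year", "index"])
    mapping = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            mapping[int(row.year)] = float(row.index)
        except ValueError as exc:
            raise RowValidationError(i, str(exc)) from None
    return DeflatorSeries(mapping)


def write_deflators(series: DeflatorSeries, path) -> None:
    items = sorted(series.index.items())
    pd.DataFrame({"year": [y for y, _ in items], "index": [v for _, v in items]}).to_csv(
        path, index=False
    )


def read_equivalence(path) -> EquivalenceTable:
    frame = _load(path, ["statin", "dose_mg", "ldl_reduction_pct"])
    try:
        return EquivalenceTable.from_frame(frame)
    except (StatinCostError, ValueError) as exc:
        raise StatinCostError(f"{path}: {exc}") from None


def write_equivalence(table: EquivalenceTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_savings_table(rows: Sequence, path) -> None:
    """Serialise SavingsRow objects: one line per year plus a 'Total' line.

    If no cumulative row (``year is None``) is supplied, one is computed by
    summing the per-year rows. Empty input is an error and no file is
    written. Float columns round-trip at full precision.
    """
    rows = list(rows)
    if not rows:
        raise StatinCostError("cannot write an empty savings table")
    year_rows = [r for r in rows if r.year is not None]
    total_rows = [r for r in rows if r.year is None]
    if not total_rows:
        from .simulation import cumulative_row

        total_rows = [cumulative_row(year_rows)]
    out = year_rows + total_rows
    pd.DataFrame(
        {
            "year": ["Total" if r.year is None else r.year for r in out],
            "n_patients": [r.n_patients for r in out],
            "actual_cost": [r.actual_cost for r in out],
            "hypothetical_cost": [r.hypothetical_cost for r in out],
            "savings_abs": [r.savings_abs for r in out],
            "savings_pct": ["" if r.savings_pct is None else repr(r.savings_pct) for r in out],
        }
    ).to_csv(path, index=False)


def read_savings_table(path) -> list:
    from .simulation import SavingsRow

    frame = _load(path, SAVINGS_COLUMNS)
    rows = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            pct = str(row.savings_pct).strip()
            rows.append(
                SavingsRow(
                    year=None if str(row.year).strip() == "Total" else int(row.year),
                    n_patients=float(row.n_patients),
                    actual_cost=float(row.actual_cost),
                    hypothetical_cost=float(row.hypothetical_cost),
                    savings_abs=float(row.savings_abs),
                    savings_pct=None if pct == "" else float(pct),
                )
            )
        except ValueError as exc:
            raise RowValidationError(i, str(exc)) from None
    return rows
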