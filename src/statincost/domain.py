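"""Core domain types for statin prescription costing.

The vocabulary mirrors English primary-care dispensing data: monthly
prescription events per patient and practice, annual price/quantity cells
per drug strength on a net-ingredient-cost (NIC) basis, WHO defined daily
doses (DDD), a GDP-deflator series used to express money in constant 2018
GBP, and the cost-effective comparator policy (simvastatin before May 2012,
atorvastatin from May 2012 onwards).

Calendar months are the finest time unit; they are represented as
:class:`pandas.Period` objects with monthly frequency and serialised as
ISO ``"YYYY-MM"`` strings.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import StatinCostError

__all__ = [
    "Statin",
    "Month",
    "month",
    "quarter",
    "month_range",
    "DEFAULT_DDD_MG",
    "DEFAULT_STRENGTHS_MG",
    "PrescriptionRecord",
    "PriceCell",
    "DddTable",
    "DeflatorSeries",
    "ComparatorPolicy",
    "BASE_YEAR",
    "records_to_frame",
    "frame_to_records",
    "RECORD_COLUMNS",
]


class Statin(enum.StrEnum):
    """The five statins available in the British National Formulary."""

    SIMVASTATIN = "simvastatin"
    ATORVASTATIN = "atorvastatin"
    ROSUVASTATIN = "rosuvastatin"
    PRAVASTATIN = "pravastatin"
    FLUVASTATIN = "fluvastatin"

    @classmethod
    def parse(cls, value: object) -> "Statin":
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise StatinCostError(f"unknown statin {value!r}") from None


#: WHO defined daily dose, milligrams, per statin.
DEFAULT_DDD_MG: Mapping[Statin, float] = {
    Statin.ATORVASTATIN: 20.0,
    Statin.FLUVASTATIN: 60.0,
    Statin.PRAVASTATIN: 30.0,
    Statin.ROSUVASTATIN: 10.0,
    Statin.SIMVASTATIN: 30.0,
}

#: Tablet strengths (mg) marketed for each statin; overridable everywhere it
#: is consumed.
DEFAULT_STRENGTHS_MG: Mapping[Statin, tuple[float, ...]] = {
    Statin.SIMVASTATIN: (10.0, 20.0, 40.0, 80.0),
    Statin.ATORVASTATIN: (10.0, 20.0, 40.0, 80.0),
    Statin.ROSUVASTATIN: (5.0, 10.0, 20.0, 40.0),
    Statin.PRAVASTATIN: (10.0, 20.0, 40.0),
    Statin.FLUVASTATIN: (20.0, 40.0, 80.0),
}

#: Money is expressed in constant GBP of this year throughout.
BASE_YEAR = 2018

Month = pd.Period

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")
_QUARTER_RE = re.compile(r"^(?:(\d{4})Q([1-4])|Q([1-4])-(\d{4}))$", re.IGNORECASE)


def month(value: object) -> pd.Period:
    """Parse a calendar month from a ``"YYYY-MM"`` string or monthly Period."""
    if isinstance(value, pd.Period):
        if value.freqstr.startswith("M"):
            return value
        raise StatinCostError(f"expected a monthly period, got freq {value.freqstr}")
    s = str(value).strip()
    if not _MONTH_RE.match(s):
        raise StatinCostError(f"invalid month {value!r}; expected 'YYYY-MM'")
    return pd.Period(s, freq="M")


def quarter(value: object) -> pd.Period:
    """Parse a calendar quarter from ``"2003Q3"`` / ``"Q3-2003"`` or a Period."""
    if isinstance(value, pd.Period):
        if value.freqstr.startswith("Q"):
            return value
        if value.freqstr.startswith("M"):
            return value.asfreq("Q")
        raise StatinCostError(f"expected a quarterly period, got freq {value.freqstr}")
    m = _QUARTER_RE.match(str(value).strip())
    if not m:
        raise StatinCostError(f"invalid quarter {value!r}; expected 'YYYYQn' or 'Qn-YYYY'")
    year, q = (m.group(1), m.group(2)) if m.group(1) else (m.group(4), m.group(3))
    return pd.Period(f"{year}Q{q}", freq="Q")


def month_range(start: object, end: object) -> pd.PeriodIndex:
    """Inclusive range of calendar months."""
    return pd.period_range(month(start), month(end), freq="M")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing event.

    ``first_episode`` marks the patient's first-ever statin prescription;
    the first-28-days savings scenario is restricted to these records.
    """

    patient_id: str
    practice_id: str
    issue_month: pd.Period
    statin: Statin
    strength_mg: float
    tablets: int
    days_supplied: int
    first_episode: bool

    def __post_init__(self):
        object.__setattr__(self, "issue_month", month(self.issue_month))
        object.__setattr__(self, "statin", Statin.parse(self.statin))
        if self.strength_mg <= 0:
            raise StatinCostError(f"strength_mg must be positive, got {self.strength_mg}")
        if int(self.tablets) != self.tablets or self.tablets <= 0:
            raise StatinCostError(f"tablets must be a positive integer, got {self.tablets}")
        if int(self.days_supplied) != self.days_supplied or self.days_supplied < 1:
            raise StatinCostError(f"days_supplied must be >= 1, got {self.days_supplied}")


@dataclass(frozen=True)
class PriceCell:
    """Annual total dispensed quantity and NIC spend for one drug strength."""

    year: int
    statin: Statin
    strength_mg: float
    total_quantity: float  # tablets
    total_spend: float  # nominal GBP

    def __post_init__(self):
        object.__setattr__(self, "statin", Statin.parse(self.statin))
        if self.strength_mg <= 0:
            raise StatinCostError(f"strength_mg must be positive, got {self.strength_mg}")
        if self.total_quantity <= 0:
            raise StatinCostError(f"total_quantity must be positive, got {self.total_quantity}")
        if self.total_spend < 0:
            raise StatinCostError(f"total_spend must be non-negative, got {self.total_spend}")

    @property
    def key(self) -> tuple[int, Statin, float]:
        return (self.year, self.statin, self.strength_mg)


@dataclass(frozen=True)
class DddTable:
    """Mapping statin -> WHO defined daily dose in milligrams."""

    ddd_mg: Mapping[Statin, float] = field(default_factory=lambda: dict(DEFAULT_DDD_MG))

    def __post_init__(self):
        clean = {Statin.parse(s): float(v) for s, v in self.ddd_mg.items()}
        for s, v in clean.items():
            if v <= 0:
                raise StatinCostError(f"DDD for {s} must be positive, got {v}")
        object.__setattr__(self, "ddd_mg", clean)

    def __getitem__(self, statin: Statin) -> float:
        return self.ddd_mg[Statin.parse(statin)]

    @classmethod
    def default(cls) -> "DddTable":
        return cls()


@dataclass(frozen=True)
class DeflatorSeries:
    """GDP-deflator index by calendar year, base 2018 = 100.

    Money amounts are converted to constant 2018 GBP by multiplying by
    ``100 / index(year)``. No extrapolation outside the listed years.
    """

    index: Mapping[int, float]

    def __post_init__(self):
        clean = {int(y): float(v) for y, v in self.index.items()}
        for y, v in clean.items():
            if v <= 0:
                raise StatinCostError(f"deflator index for {y} must be positive, got {v}")
        if BASE_YEAR not in clean:
            raise StatinCostError(f"deflator series must include the base year {BASE_YEAR}")
        if abs(clean[BASE_YEAR] - 100.0) > 1e-9:
            raise StatinCostError(
                f"deflator index for base year {BASE_YEAR} must be 100, got {clean[BASE_YEAR]}"
            )
        object.__setattr__(self, "index", clean)

    def __contains__(self, year: int) -> bool:
        return int(year) in self.index

    def factor_to_base(self, year: int) -> float:
        from .errors import MissingDeflatorError

        y = int(year)
        if y not in self.index:
            raise MissingDeflatorError(f"no deflator index for year {y}")
        return 100.0 / self.index[y]


@dataclass(frozen=True)
class ComparatorPolicy:
    """The policy-designated cost-effective statin over time.

    Simvastatin before the cutover month, atorvastatin from the cutover
    onwards (the cutover month itself maps to the post comparator).
    """

    cutover_month: pd.Period = pd.Period("2012-05", freq="M")
    pre_comparator: Statin = Statin.SIMVASTATIN
    post_comparator: Statin = Statin.ATORVASTATIN

    def __post_init__(self):
        object.__setattr__(self, "cutover_month", month(self.cutover_month))
        object.__setattr__(self, "pre_comparator", Statin.parse(self.pre_comparator))
        object.__setattr__(self, "post_comparator", Statin.parse(self.post_comparator))
        if self.pre_comparator == self.post_comparator:
            raise StatinCostError("pre and post comparators must differ")


RECORD_COLUMNS = [
    "patient_id",
    "practice_id",
    "issue_month",
    "statin",
    "strength_mg",
    "tablets",
    "days_supplied",
    "first_episode",
]


def records_to_frame(records: Iterable[PrescriptionRecord] | pd.DataFrame) -> pd.DataFrame:
    """Canonical DataFrame view of a record collection.

    Accepts either an iterable of :class:`PrescriptionRecord` or an
    already-built frame with the canonical columns (returned as-is after a
    column check), so every analysis entry point takes both forms.
    """
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLUMNS if c not in records.columns]
        if missing:
            raise StatinCostError(f"record frame missing columns: {missing}")
        return records
    rows = list(records)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "practice_id": [r.practice_id for r in rows],
            "issue_month": pd.PeriodIndex([r.issue_month for r in rows], freq="M")
            if rows
            else pd.PeriodIndex([], freq="M"),
            "statin": [str(r.statin) for r in rows],
            "strength_mg": [r.strength_mg for r in rows],
            "tablets": [r.tablets for r in rows],
            "days_supplied": [r.days_supplied for r in rows],
            "first_episode": [r.first_episode for r in rows],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[PrescriptionRecord]:
    return [
        PrescriptionRecord(
            patient_id=str(row.patient_id),
            practice_id=str(row.practice_id),
            issue_month=month(row.issue_month),
            statin=Statin.parse(row.statin),
            strength_mg=float(row.strength_mg),
            tablets=int(row.tablets),
            days_supplied=int(row.days_supplied),
            first_episode=bool(row.first_episode),
        )
        for row in frame.itertuples(index=False)
    ]
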