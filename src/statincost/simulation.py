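"""Actual vs counterfactual cost accounting under the comparator policy.

Two scenarios mirror the two panels of the spending-simulation table:

* first-episode — only records flagged as a patient's first prescription
  episode, costed for the first 28 days of treatment;
* all-patients  — every record of every patient, uncapped.

The counterfactual reprices each record as if the policy comparator
(simvastatin before the cutover, atorvastatin from it onwards) had been
prescribed at the therapeutically similar dose, keeping tablet count and
duration. Records already on the comparator are costed unchanged. Costs
use the strength-year average acquisition cost and are expressed in
constant 2018 GBP; savings are actual minus hypothetical, absolute and as
a percentage of actual spend. The substitution is evaluated per record at
its own issue month, so a patient whose records straddle the cutover is
handled correctly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .domain import (
    ComparatorPolicy,
    DeflatorSeries,
    PrescriptionRecord,
    PriceCell,
    Statin,
    records_to_frame,
)
from .equivalence import EquivalenceTable, comparator_for, substitute
from .errors import MissingPriceError, StatinCostError
from .pricing import unit_cost_index

__all__ = [
    "SavingsRow",
    "episode_cost",
    "hypothetical_episode_cost",
    "scenario_first_episode",
    "scenario_all_patients",
    "cumulative_row",
    "scale_to_national",
    "FIRST_EPISODE_CAP_DAYS",
]

#: Day cap for the first-episode scenario.
FIRST_EPISODE_CAP_DAYS = 28


@dataclass(frozen=True)
class SavingsRow:
    """One year (or the cumulative 'Total' when ``year`` is None) of the
    savings table: actual and counterfactual constant-2018-GBP cost and the
    implied absolute and relative savings."""

    year: int | None
    n_patients: float
    actual_cost: float
    hypothetical_cost: float
    savings_abs: float
    savings_pct: float | None

    def __post_init__(self):
        expected = self.actual_cost - self.hypothetical_cost
        tol = 1e-6 * max(1.0, abs(self.actual_cost), abs(self.hypothetical_cost))
        if abs(self.savings_abs - expected) > tol:
            raise StatinCostError(
                f"savings_abs {self.savings_abs} != actual - hypothetical {expected}"
            )


def _charged_tablets(tablets: float, days_supplied: float, cap_days: int | None) -> float:
    """Tablets charged under a day cap, prorated by day fraction."""
    if cap_days is None:
        return float(tablets)
    return float(tablets) * min(float(days_supplied), float(cap_days)) / float(days_supplied)


def _as_index(prices) -> Mapping[tuple[Statin, float, int], float]:
    if isinstance(prices, Mapping):
        return prices
    return unit_cost_index(prices)


def _lookup(index, statin: Statin, strength: float, year: int) -> float:
    try:
        return index[(statin, float(strength), int(year))]
    except KeyError:
        raise MissingPriceError(
            f"no price for {statin} {strength} mg in {year}"
        ) from None


def episode_cost(
    record: PrescriptionRecord,
    cap_days: int | None,
    prices: Iterable[PriceCell] | Mapping,
    deflators: DeflatorSeries,
) -> float:
    """Constant-2018-GBP cost of one record, optionally capped to ``cap_days``."""
    index = _as_index(prices)
    year = record.issue_month.year
    uc = _lookup(index, record.statin, record.strength_mg, year)
    charged = _charged_tablets(record.tablets, record.days_supplied, cap_days)
    return charged * uc * deflators.factor_to_base(year)


def hypothetical_episode_cost(
    record: PrescriptionRecord,
    cap_days: int | None,
    prices: Iterable[PriceCell] | Mapping,
    equivalence: EquivalenceTable,
    policy: ComparatorPolicy,
    deflators: DeflatorSeries,
) -> float:
    """Cost of the record had the comparator been prescribed instead.

    Same tablet count and duration; agent and strength substituted via the
    LDL-equivalence table. A record already on the comparator is a fixed
    point.
    """
    comparator = comparator_for(record.issue_month, policy)
    if record.statin == comparator:
        return episode_cost(record, cap_days, prices, deflators)
    index = _as_index(prices)
    sub = substitute(record.statin, record.strength_mg, comparator, equivalence)
    year = record.issue_month.year
    uc = _lookup(index, sub.statin, sub.dose_mg, year)
    charged = _charged_tablets(record.tablets, record.days_supplied, cap_days)
    return charged * uc * deflators.factor_to_base(year)


def _scenario(
    frame: pd.DataFrame,
    included: pd.DataFrame,
    cap_days: int | None,
    prices,
    equivalence: EquivalenceTable,
    policy: ComparatorPolicy,
    deflators: DeflatorSeries,
    scale: float | None,
    count_mode: str,
) -> list[SavingsRow]:
    index = _as_index(prices)
    factor = 1.0 if scale is None else float(scale)

    months = pd.PeriodIndex(included["issue_month"], freq="M")
    years = months.year.to_numpy()
    statins = included["statin"].astype(str).to_numpy()
    strengths = included["strength_mg"].astype(float).to_numpy()
    tablets = included["tablets"].astype(float).to_numpy()
    days = included["days_supplied"].astype(float).to_numpy()

    pre, post = str(policy.pre_comparator), str(policy.post_comparator)
    comp = np.where(months < policy.cutover_month, pre, post)

    # substitution map over the distinct (source statin, strength, comparator)
    sub_cache: dict[tuple[str, float, str], tuple[str, float]] = {}
    for s, m, c in {(a, b, d) for a, b, d in zip(statins, strengths, comp)}:
        sub = substitute(Statin.parse(s), m, Statin.parse(c), equivalence)
        sub_cache[(s, m, c)] = (str(sub.statin), sub.dose_mg)

    if cap_days is None:
        charged = tablets
    else:
        charged = tablets * np.minimum(days, float(cap_days)) / days
    defl = np.array([deflators.factor_to_base(y) for y in years])
    uc_actual = np.array(
        [
            _lookup(index, Statin.parse(s), m, y)
            for s, m, y in zip(statins, strengths, years)
        ]
    )
    hyp_pairs = [sub_cache[(s, m, c)] for s, m, c in zip(statins, strengths, comp)]
    uc_hyp = np.array(
        [
            _lookup(index, Statin.parse(hs), hm, y)
            for (hs, hm), y in zip(hyp_pairs, years)
        ]
    )

    actual = charged * uc_actual * defl * factor
    hyp = charged * uc_hyp * defl * factor

    all_years = pd.PeriodIndex(frame["issue_month"], freq="M").year
    year_span = (
        range(int(all_years.min()), int(all_years.max()) + 1) if len(frame) else []
    )
    per_year = pd.DataFrame({"year": years, "actual": actual, "hyp": hyp})
    sums = per_year.groupby("year").sum()

    if count_mode == "first_episodes":
        n_by_year = pd.Series(years).value_counts()
        n_total = float(len(included))
    else:
        pat = included["patient_id"].astype(str)
        n_by_year = pd.DataFrame({"year": years, "pat": pat.to_numpy()}).groupby("year")[
            "pat"
        ].nunique()
        n_total = float(pat.nunique())

    rows: list[SavingsRow] = []
    for y in year_span:
        a = float(sums["actual"].get(y, 0.0))
        h = float(sums["hyp"].get(y, 0.0))
        n = float(n_by_year.get(y, 0)) * factor
        sav = a - h
        pct = 100.0 * sav / a if a > 0 else None
        rows.append(SavingsRow(int(y), n, a, h, sav, pct))
    rows.append(cumulative_row(rows, n_patients=n_total * factor))
    return rows


def cumulative_row(year_rows: Iterable[SavingsRow], n_patients: float | None = None) -> SavingsRow:
    """Cumulative 'Total' row over per-year rows.

    ``n_patients`` defaults to the sum of the per-year counts, which is
    correct for first-episode counts but double-counts multi-year patients;
    the scenario functions pass the distinct-patient total explicitly.
    """
    year_rows = [r for r in year_rows if r.year is not None]
    a = sum(r.actual_cost for r in year_rows)
    h = sum(r.hypothetical_cost for r in year_rows)
    n = sum(r.n_patients for r in year_rows) if n_patients is None else n_patients
    sav = a - h
    pct = 100.0 * sav / a if a > 0 else None
    return SavingsRow(None, n, a, h, sav, pct)


def scenario_first_episode(
    records: Iterable[PrescriptionRecord] | pd.DataFrame,
    prices: Iterable[PriceCell] | Mapping,
    equivalence: EquivalenceTable,
    policy: ComparatorPolicy | None = None,
    deflators: DeflatorSeries | None = None,
    *,
    cap_days: int | None = FIRST_EPISODE_CAP_DAYS,
    scale: float | None = None,
) -> list[SavingsRow]:
    """Savings on the first 28 days of treatment of new patients, per year.

    ``scale`` (optional) is a sample-to-national blow-up applied to both
    patient counts and money amounts.
    """
    policy = policy or ComparatorPolicy()
    if deflators is None:
        raise StatinCostError("a deflator series is required")
    frame = records_to_frame(records)
    included = frame[frame["first_episode"].astype(bool)]
    return _scenario(
        frame, included, cap_days, prices, equivalence, policy, deflators, scale,
        "first_episodes",
    )


def scenario_all_patients(
    records: Iterable[PrescriptionRecord] | pd.DataFrame,
    prices: Iterable[PriceCell] | Mapping,
    equivalence: EquivalenceTable,
    policy: ComparatorPolicy | None = None,
    deflators: DeflatorSeries | None = None,
    *,
    scale: float | None = None,
) -> list[SavingsRow]:
    """Savings had every prescription-day of every patient been switched.

    An upper bound: it assumes ongoing patients could be switched to the
    comparator immediately and without clinical cost. ``n_patients`` counts
    distinct patients with at least one record in the year.
    """
    policy = policy or ComparatorPolicy()
    if deflators is None:
        raise StatinCostError("a deflator series is required")
    frame = records_to_frame(records)
    return _scenario(
        frame, frame, None, prices, equivalence, policy, deflators, scale,
        "distinct_patients",
    )


def scale_to_national(sample_count: float, national_total: float, sample_total: float) -> float:
    """Blow a sample count up to a national estimate by simple proportion."""
    if sample_total == 0:
        raise StatinCostError("sample_total must be non-zero to scale to national")
    return sample_count * national_total / sample_total
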