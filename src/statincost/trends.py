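"""Initiation market shares, practice-heterogeneity quintiles, and
switch-away rates.

"New patients" are records flagged ``first_episode``. Market shares are
the fraction of new patients starting on each statin per period (month or
calendar quarter). Heterogeneity across general practices is summarised by
ranking practices on their share of new patients given a focal statin and
averaging within five quintile groups — either re-ranked every period
(dynamic) or frozen at a baseline quarter (fixed), which separates overall
heterogeneity from persistence of individual practices' habits.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .domain import PrescriptionRecord, Statin, quarter, records_to_frame
from .errors import StatinCostError

__all__ = [
    "ShareSeries",
    "QuintileSeries",
    "market_shares",
    "quintile_assignments",
    "quintile_means_dynamic",
    "quintile_means_fixed",
    "switch_away_rate",
]

log = logging.getLogger(__name__)

_ALL_STATINS = [str(s) for s in Statin]


def _period_col(frame: pd.DataFrame, granularity: str) -> pd.Series:
    months = pd.PeriodIndex(frame["issue_month"], freq="M")
    if granularity == "month":
        return pd.Series(months, index=frame.index)
    if granularity == "quarter":
        return pd.Series(months.asfreq("Q"), index=frame.index)
    raise StatinCostError(f"granularity must be 'month' or 'quarter', got {granularity!r}")


@dataclass(frozen=True)
class ShareSeries:
    """Per-period initiation shares; one column per statin, rows sum to 1.

    Periods inside the observed span with no new patients are kept as
    all-NaN rows — the explicit empty marker.
    """

    shares: pd.DataFrame
    granularity: str

    @property
    def empty_periods(self) -> list:
        return list(self.shares.index[self.shares.isna().all(axis=1)])

    def share(self, statin: Statin, period) -> float:
        return float(self.shares.loc[period, str(Statin.parse(statin))])

    def to_tidy(self) -> pd.DataFrame:
        tidy = (
            self.shares.rename_axis("period")
            .reset_index()
            .melt(id_vars="period", var_name="statin", value_name="share")
            .sort_values(["period", "statin"], kind="stable")
            .reset_index(drop=True)
        )
        tidy["period"] = tidy["period"].astype(str)
        return tidy


@dataclass(frozen=True)
class QuintileSeries:
    """Per-period mean focal share in five practice groups (q1 lowest)."""

    means: pd.DataFrame  # index: period; columns q1..q5
    mode: str  # "dynamic" | "fixed_baseline"
    focal: Statin
    baseline_period: object = None

    def gap(self) -> pd.Series:
        """Top-minus-bottom quintile mean per period."""
        return self.means["q5"] - self.means["q1"]

    def to_tidy(self) -> pd.DataFrame:
        tidy = (
            self.means.rename_axis("period")
            .reset_index()
            .melt(id_vars="period", var_name="quintile", value_name="mean_share")
        )
        tidy["quintile"] = tidy["quintile"].str.lstrip("q").astype(int)
        tidy["mode"] = self.mode
        tidy["period"] = tidy["period"].astype(str)
        return tidy.sort_values(["period", "quintile"], kind="stable").reset_index(drop=True)


def market_shares(
    records: Iterable[PrescriptionRecord] | pd.DataFrame, granularity: str = "month"
) -> ShareSeries:
    """Share of new patients initiating on each statin, per period.

    The period span covers all input records (not only first episodes), so
    periods with prescribing activity but no initiations appear as empty.
    """
    frame = records_to_frame(records)
    if frame.empty:
        empty = pd.DataFrame(columns=_ALL_STATINS, index=pd.PeriodIndex([], freq="M"))
        return ShareSeries(empty, granularity)
    periods = _period_col(frame, granularity)
    span = pd.period_range(periods.min(), periods.max())
    fe = frame[frame["first_episode"].astype(bool)]
    if fe.empty:
        counts = pd.DataFrame(0, index=span, columns=_ALL_STATINS)
    else:
        counts = (
            pd.crosstab(periods[fe.index], fe["statin"])
            .reindex(span, fill_value=0)
            .reindex(columns=_ALL_STATINS, fill_value=0)
        )
    totals = counts.sum(axis=1)
    shares = counts.div(totals.replace(0, np.nan), axis=0)
    shares.index.name = "period"
    return ShareSeries(shares, granularity)


def quintile_assignments(shares: pd.Series) -> pd.Series:
    """Partition practices into quintile groups 1..5 by ascending share.

    Cut points are at ranks ceil(k*N/5); ties are broken by practice
    identifier so the partition is deterministic.
    """
    order = shares.reset_index()
    order.columns = ["practice_id", "share"]
    order = order.sort_values(["share", "practice_id"], kind="stable").reset_index(drop=True)
    n = len(order)
    if n == 0:
        return pd.Series(dtype=int)
    bounds = [math.ceil(k * n / 5) for k in range(1, 6)]
    ranks = np.arange(1, n + 1)
    groups = np.searchsorted(bounds, ranks, side="left") + 1
    return pd.Series(groups, index=order["practice_id"].values, dtype=int)


def _practice_shares(fe: pd.DataFrame, focal: Statin) -> pd.Series:
    """Per-practice share of new patients on the focal statin."""
    totals = fe.groupby("practice_id").size()
    focal_counts = fe[fe["statin"] == str(focal)].groupby("practice_id").size()
    return (focal_counts.reindex(totals.index, fill_value=0) / totals).astype(float)


def quintile_means_dynamic(
    records: Iterable[PrescriptionRecord] | pd.DataFrame,
    focal: Statin,
    granularity: str = "month",
    min_practices: int = 5,
) -> QuintileSeries:
    """Quintile means with practices re-ranked every period.

    Periods with fewer than ``min_practices`` practices having any new
    patient are skipped with a log notice.
    """
    focal = Statin.parse(focal)
    frame = records_to_frame(records)
    fe = frame[frame["first_episode"].astype(bool)].copy()
    fe["period"] = _period_col(fe, granularity)
    rows = {}
    for period, group in fe.groupby("period"):
        shares = _practice_shares(group, focal)
        if len(shares) < min_practices:
            log.info("skipping %s: only %d practices with new patients", period, len(shares))
            continue
        groups = quintile_assignments(shares)
        means = shares.groupby(groups).mean()
        rows[period] = {f"q{g}": means.get(g, np.nan) for g in range(1, 6)}
    means = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    means.index.name = "period"
    return QuintileSeries(means, "dynamic", focal)


def quintile_means_fixed(
    records: Iterable[PrescriptionRecord] | pd.DataFrame,
    focal: Statin,
    baseline_period,
    granularity: str = "month",
    min_practices: int = 5,
) -> QuintileSeries:
    """Quintile means with group membership frozen at a baseline quarter.

    Membership is computed once from the focal shares over the baseline
    quarter; thereafter each period reports the unweighted mean focal share
    of the practices in each fixed group that are active in that period.
    """
    focal = Statin.parse(focal)
    baseline = quarter(baseline_period)
    frame = records_to_frame(records)
    fe = frame[frame["first_episode"].astype(bool)].copy()
    fe["period"] = _period_col(fe, granularity)
    base = fe[_period_col(fe, "quarter") == baseline]
    base_shares = _practice_shares(base, focal)
    if len(base_shares) < min_practices:
        raise StatinCostError(
            f"baseline quarter {baseline} has only {len(base_shares)} practices "
            f"with new patients (need >= {min_practices})"
        )
    membership = quintile_assignments(base_shares)
    rows = {}
    for period, group in fe.groupby("period"):
        shares = _practice_shares(group, focal)
        shares = shares[shares.index.isin(membership.index)]
        if shares.empty:
            continue
        means = shares.groupby(membership.reindex(shares.index)).mean()
        rows[period] = {f"q{g}": means.get(g, np.nan) for g in range(1, 6)}
    means = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    means.index.name = "period"
    return QuintileSeries(means, "fixed_baseline", focal, baseline)


def switch_away_rate(
    records: Iterable[PrescriptionRecord] | pd.DataFrame,
    target: Statin,
    window_months: int,
) -> float | None:
    """Percentage of switch-to-target patients who leave it again in time.

    A patient enters the denominator at their first record of ``target``
    immediately preceded by a different statin; they enter the numerator if
    any later record within ``window_months`` of that switch is a
    non-target statin. Patients never prescribed again stay in the
    denominator only. Returns None (undefined) when nobody switches to the
    target.
    """
    target = Statin.parse(target)
    frame = records_to_frame(records)
    if frame.empty:
        return None
    frame = frame.sort_values(["patient_id", "issue_month"], kind="stable")
    denominator = 0
    numerator = 0
    for _, group in frame.groupby("patient_id", sort=False):
        statins = group["statin"].tolist()
        months = list(pd.PeriodIndex(group["issue_month"], freq="M"))
        switch_at = None
        for i in range(1, len(statins)):
            if statins[i] == str(target) and statins[i - 1] != str(target):
                switch_at = i
                break
        if switch_at is None:
            continue
        denominator += 1
        limit = months[switch_at] + window_months
        for j in range(switch_at + 1, len(statins)):
            if months[j] > limit:
                break
            if statins[j] != str(target):
                numerator += 1
                break
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator
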