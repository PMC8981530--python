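"""Configuration-driven pipeline tying the stages together.

``run_pipeline`` reads (or synthesises) the five input tables, then writes
the cost-per-DDD series, initiation share series, dynamic and
baseline-fixed quintile series, and the savings tables for one or both
scenarios, plus optional figures. It returns a manifest mapping each
produced file to its SHA-256 hash; identical configuration and seed give
identical manifests. Any stage failure removes partial outputs and
re-raises with the stage name.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import io as dio
from .domain import ComparatorPolicy, DddTable, Statin, quarter
from .equivalence import EquivalenceTable
from .errors import StatinCostError
from .pricing import cost_per_ddd_series
from .simulation import (
    SavingsRow,
    cumulative_row,
    scenario_all_patients,
    scenario_first_episode,
)
from .synthetic import (
    CohortConfig,
    default_price_dynamics,
    generate_cohort,
    generate_price_series,
    synthetic_deflators,
)
from .trends import market_shares, quintile_means_dynamic, quintile_means_fixed

__all__ = ["PipelineConfig", "run_pipeline", "render_table1"]

log = logging.getLogger(__name__)


class InputPaths(BaseModel):
    prescriptions: Path
    prices: Path
    ddd: Optional[Path] = None
    deflator: Path
    equivalence: Optional[Path] = None


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    mode: Literal["synthetic", "files"] = "synthetic"
    inputs: Optional[InputPaths] = None
    seed: int = 0
    cutover_month: str = "2012-05"
    pre_comparator: str = "simvastatin"
    post_comparator: str = "atorvastatin"
    scenario: Literal["first", "all", "both"] = "both"
    granularity: Literal["month", "quarter"] = "month"
    quintile_granularity: Literal["month", "quarter"] = "quarter"
    baseline_quarter: str = "2003Q3"
    focal_statin: str = "simvastatin"
    out_dir: Path = Path("statincost-output")
    scale: Optional[float] = None
    plots: bool = False
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_paths(self):
        if self.mode == "files":
            if self.inputs is None:
                raise ValueError("mode 'files' requires input paths")
            for name in ("prescriptions", "prices", "deflator"):
                p = getattr(self.inputs, name)
                if not Path(p).exists():
                    raise ValueError(f"input file for {name!r} not found: {p}")
            for name in ("ddd", "equivalence"):
                p = getattr(self.inputs, name)
                if p is not None and not Path(p).exists():
                    raise ValueError(f"input file for {name!r} not found: {p}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def policy(self) -> ComparatorPolicy:
        return ComparatorPolicy(
            cutover_month=self.cutover_month,
            pre_comparator=Statin.parse(self.pre_comparator),
            post_comparator=Statin.parse(self.post_comparator),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.mode == "synthetic":
        prices = generate_price_series(default_price_dynamics(), seed=config.seed)
        years = sorted({c.year for c in prices})
        deflators = synthetic_deflators(years)
        cohort = CohortConfig(seed=config.seed)
        records = generate_cohort(cohort, prices, deflators, policy=config.policy())
        ddd = DddTable.default()
        table = EquivalenceTable.default()
        return records, prices, ddd, deflators, table
    inputs = config.inputs
    records = dio.read_prescriptions(inputs.prescriptions)
    prices = dio.read_prices(inputs.prices)
    ddd = dio.read_ddd_table(inputs.ddd) if inputs.ddd else DddTable.default()
    deflators = dio.read_deflators(inputs.deflator)
    table = (
        dio.read_equivalence(inputs.equivalence)
        if inputs.equivalence
        else EquivalenceTable.default()
    )
    return records, prices, ddd, deflators, table


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every configured stage; return {relative path: sha256}."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load-inputs"
    try:
        t0 = time.perf_counter()
        records, prices, ddd, deflators, table = _load_inputs(config)
        policy = config.policy()
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        def emit(name: str, writer) -> None:
            path = out / name
            writer(path)
            written.append(path)

        stage = "cost-per-ddd"
        series = cost_per_ddd_series(prices, ddd, deflators)
        emit("cost_per_ddd.csv", lambda p: series.to_csv(p, index=False))

        stage = "market-shares"
        shares = market_shares(records, granularity=config.granularity)
        emit("market_shares.csv", lambda p: shares.to_tidy().to_csv(p, index=False))

        stage = "quintiles"
        focal = Statin.parse(config.focal_statin)
        dyn = quintile_means_dynamic(
            records, focal, granularity=config.quintile_granularity
        )
        emit("quintiles_dynamic.csv", lambda p: dyn.to_tidy().to_csv(p, index=False))
        fixed = quintile_means_fixed(
            records,
            focal,
            quarter(config.baseline_quarter),
            granularity=config.quintile_granularity,
        )
        emit("quintiles_fixed.csv", lambda p: fixed.to_tidy().to_csv(p, index=False))

        first_rows = all_rows = None
        if config.scenario in ("first", "both"):
            stage = "savings-first-episode"
            first_rows = scenario_first_episode(
                records, prices, table, policy, deflators, scale=config.scale
            )
            emit(
                "savings_first_episode.csv",
                lambda p: dio.write_savings_table(first_rows, p),
            )
        if config.scenario in ("all", "both"):
            stage = "savings-all-patients"
            all_rows = scenario_all_patients(
                records, prices, table, policy, deflators, scale=config.scale
            )
            emit(
                "savings_all_patients.csv",
                lambda p: dio.write_savings_table(all_rows, p),
            )
        if first_rows is not None and all_rows is not None:
            stage = "table1"
            text = render_table1(first_rows, all_rows)
            emit("table1.txt", lambda p: p.write_text(text, encoding="utf-8"))

        if config.plots:
            stage = "plots"
            for name, fig in _figures(series, shares, dyn, fixed):
                emit(name, lambda p, f=fig: f.savefig(p, metadata={"Date": None}))

        stage = "manifest"
        manifest = {p.name: _sha256(p) for p in written}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StatinCostError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _figures(ddd_series: pd.DataFrame, shares, dyn, fixed):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "statincost"
    figs = []

    fig, ax = plt.subplots(figsize=(8, 4))
    for statin, grp in shares.shares.items():
        ax.plot(shares.shares.index.astype(str), grp.values, label=statin)
    ax.set_ylabel("share of new patients")
    ax.legend(fontsize=7)
    ax.set_xticks(ax.get_xticks()[:: max(1, len(shares.shares) // 8)])
    figs.append(("fig_shares.svg", fig))

    fig, ax = plt.subplots(figsize=(8, 4))
    for statin, grp in ddd_series.groupby("statin"):
        ax.plot(grp["year"], grp["cost_per_ddd"], label=statin)
    ax.set_ylabel("GBP per DDD (2018 prices)")
    ax.legend(fontsize=7)
    figs.append(("fig_cost_per_ddd.svg", fig))

    for name, qs in (("fig_quintiles_dynamic.svg", dyn), ("fig_quintiles_fixed.svg", fixed)):
        fig, ax = plt.subplots(figsize=(8, 4))
        for col in qs.means.columns:
            ax.plot(qs.means.index.astype(str), qs.means[col], label=col)
        ax.set_ylabel("mean focal share")
        ax.legend(fontsize=7)
        ax.set_xticks(ax.get_xticks()[:: max(1, len(qs.means) // 8)])
        figs.append((name, fig))
    return figs


def _fmt_money(x: float) -> str:
    return f"{x:,.2f}"


def render_table1(first_rows: list[SavingsRow], all_rows: list[SavingsRow]) -> str:
    """Two-panel text table: first-episode scenario left, all-patients right.

    One row per year plus the cumulative row; money in constant 2018 GBP.
    """
    if not first_rows or not all_rows:
        raise StatinCostError("both scenarios are required to render the table")
    f_years = [r.year for r in first_rows if r.year is not None]
    a_years = [r.year for r in all_rows if r.year is not None]
    if f_years != a_years:
        raise StatinCostError(f"year sets differ between panels: {f_years} vs {a_years}")

    def total(rows):
        tot = [r for r in rows if r.year is None]
        return tot[0] if tot else cumulative_row(rows)

    by_year_f = {r.year: r for r in first_rows if r.year is not None}
    by_year_a = {r.year: r for r in all_rows if r.year is not None}
    header = (
        f"{'':6} | {'first prescription episode (28-day cap)':^58} | "
        f"{'all patients, all prescription-days':^58}"
    )
    sub = (
        f"{'year':>6} | {'n':>10} {'actual':>14} {'hypothetical':>14} "
        f"{'savings':>12} {'%':>5} | {'n':>10} {'actual':>14} "
        f"{'hypothetical':>14} {'savings':>12} {'%':>5}"
    )
    lines = [header, sub, "-" * len(sub)]

    def panel(r: SavingsRow) -> str:
        pct = "" if r.savings_pct is None else f"{r.savings_pct:5.1f}"
        return (
            f"{r.n_patients:>10,.0f} {_fmt_money(r.actual_cost):>14} "
            f"{_fmt_money(r.hypothetical_cost):>14} {_fmt_money(r.savings_abs):>12} {pct:>5}"
        )

    for y in f_years:
        lines.append(f"{y:>6} | {panel(by_year_f[y])} | {panel(by_year_a[y])}")
    lines.append(f"{'Total':>6} | {panel(total(first_rows))} | {panel(total(all_rows))}")
    return "\n".join(lines) + "\n"
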