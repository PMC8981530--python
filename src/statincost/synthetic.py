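"""Seeded generator of price series and prescription cohorts.

The generator emulates the statistical structure of English primary-care
statin data over 2003-07 to 2018-12:

* **Prices.** Each statin has a branded real price per DDD; after patent
  expiry the price decays geometrically per quarter down to a floor
  fraction of the branded price (generic-entry dynamics). Tablet prices
  scale sublinearly with strength (exponent 0.8), annual dispensed
  quantities are drawn log-normally, and spend is quoted in nominal GBP so
  the analysis pipeline has to deflate it, as with real NIC data. The
  default configuration carries the two expiries that shaped the market:
  simvastatin (May 2003) and atorvastatin (May 2012).

* **Prescriber choice.** Each practice holds latent preferences
  alpha(p, s) ~ Normal(0, sigma^2). New patients arrive Poisson per
  practice-month; the initial statin follows multinomial-logit
  probabilities proportional to
  ``exp(alpha(p, s) - beta * price_per_DDD(s, t) + gamma * recommended(s, t))``,
  where the recommendation history defaults to simvastatin from the first
  national guidance (January 2006) and atorvastatin from the May 2014
  update.

* **Persistence.** Patients receive one 28-tablet prescription per month
  at the statin's modal strength until discontinuation (geometric with a
  monthly hazard), switching to the current policy comparator each month
  with a configured probability. The first record carries the
  first-episode flag.

Everything is deterministic given the integer seed: a single
``numpy.random.Generator`` is threaded through all draws in a fixed order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .domain import (
    BASE_YEAR,
    DEFAULT_STRENGTHS_MG,
    ComparatorPolicy,
    DddTable,
    DeflatorSeries,
    PriceCell,
    Statin,
    month,
    month_range,
)
from .errors import StatinCostError
from .pricing import cost_per_ddd, deflate

__all__ = [
    "StatinPriceDynamics",
    "PriceDynamicsConfig",
    "default_price_dynamics",
    "real_price_per_ddd",
    "real_price_per_tablet",
    "generate_price_series",
    "synthetic_deflators",
    "GuidelineHistory",
    "default_guideline_history",
    "CohortConfig",
    "default_yearly_volumes",
    "logit_choice_probabilities",
    "generate_cohort",
    "fit_choice_model",
    "STATIN_ORDER",
]

STATIN_ORDER: tuple[Statin, ...] = (
    Statin.SIMVASTATIN,
    Statin.ATORVASTATIN,
    Statin.ROSUVASTATIN,
    Statin.PRAVASTATIN,
    Statin.FLUVASTATIN,
)

DEFAULT_WINDOW = ("2003-07", "2018-12")


@dataclass(frozen=True)
class StatinPriceDynamics:
    """Generic-entry price path for one statin.

    Real (constant-2018 GBP) price per DDD is the branded level until
    patent expiry, then multiplied by ``decay_per_quarter`` for every
    completed quarter since expiry, floored at ``floor_fraction`` of the
    branded price.
    """

    branded_real_per_ddd: float
    patent_expiry: pd.Period | None = None
    decay_per_quarter: float = 0.75
    floor_fraction: float = 0.05

    def __post_init__(self):
        if self.patent_expiry is not None:
            object.__setattr__(self, "patent_expiry", month(self.patent_expiry))
        if not (0 < self.decay_per_quarter <= 1):
            raise StatinCostError("decay_per_quarter must be in (0, 1]")
        if not (0 < self.floor_fraction <= 1):
            raise StatinCostError("floor_fraction must be in (0, 1]")
        if self.branded_real_per_ddd <= 0:
            raise StatinCostError("branded_real_per_ddd must be positive")


@dataclass(frozen=True)
class PriceDynamicsConfig:
    per_statin: Mapping[Statin, StatinPriceDynamics]
    strength_exponent: float = 0.8  # sublinear price-in-strength
    annual_tablets_per_strength: float = 2.0e5
    quantity_sigma: float = 0.2  # lognormal spread of annual quantities


def default_price_dynamics() -> PriceDynamicsConfig:
    """Two-expiry default emulating the observed market history."""
    return PriceDynamicsConfig(
        per_statin={
            Statin.SIMVASTATIN: StatinPriceDynamics(0.80, pd.Period("2003-05", "M")),
            Statin.ATORVASTATIN: StatinPriceDynamics(0.85, pd.Period("2012-05", "M")),
            Statin.ROSUVASTATIN: StatinPriceDynamics(0.95, None),
            Statin.PRAVASTATIN: StatinPriceDynamics(0.85, None),
            Statin.FLUVASTATIN: StatinPriceDynamics(0.90, None),
        }
    )


def real_price_per_ddd(dyn: StatinPriceDynamics, when) -> float:
    """Real GBP per DDD at a calendar month under the decay model."""
    m = month(when)
    if dyn.patent_expiry is None or m < dyn.patent_expiry:
        return dyn.branded_real_per_ddd
    quarters = (m - dyn.patent_expiry).n // 3
    return dyn.branded_real_per_ddd * max(
        dyn.floor_fraction, dyn.decay_per_quarter**quarters
    )


def real_price_per_tablet(
    config: PriceDynamicsConfig,
    statin: Statin,
    strength_mg: float,
    when,
    ddd: DddTable | None = None,
) -> float:
    """Real GBP per tablet: the per-DDD price scaled by (strength/DDD)^0.8."""
    ddd = ddd or DddTable.default()
    statin = Statin.parse(statin)
    base = real_price_per_ddd(config.per_statin[statin], when)
    return base * (float(strength_mg) / ddd[statin]) ** config.strength_exponent


def synthetic_deflators(
    years: Iterable[int], annual_inflation: float = 0.02
) -> DeflatorSeries:
    """A smooth GDP-deflator series, base 2018 = 100.

    The base year is always included so the series is valid even when the
    requested years end before 2018.
    """
    all_years = set(int(y) for y in years) | {BASE_YEAR}
    return DeflatorSeries(
        {y: 100.0 * (1 + annual_inflation) ** (y - BASE_YEAR) for y in sorted(all_years)}
    )


def generate_price_series(
    config: PriceDynamicsConfig,
    window: tuple = DEFAULT_WINDOW,
    seed: int = 0,
    *,
    ddd: DddTable | None = None,
    deflators: DeflatorSeries | None = None,
    strengths: Mapping[Statin, Sequence[float]] | None = None,
) -> list[PriceCell]:
    """Annual price/quantity cells per drug strength over the window.

    The annual nominal spend is the mean real tablet price over the year's
    twelve months, re-inflated with the deflator series and multiplied by
    the drawn quantity. Deterministic given the seed.
    """
    months = month_range(*window)
    if len(months) == 0:
        raise StatinCostError("empty price window")
    ddd = ddd or DddTable.default()
    years = sorted({m.year for m in months})
    deflators = deflators or synthetic_deflators(years)
    strengths = strengths or DEFAULT_STRENGTHS_MG
    rng = np.random.default_rng(seed)
    cells: list[PriceCell] = []
    for statin in STATIN_ORDER:
        for strength in sorted(strengths[statin]):
            for year in years:
                year_months = pd.period_range(f"{year}-01", f"{year}-12", freq="M")
                mean_real = float(
                    np.mean(
                        [
                            real_price_per_tablet(config, statin, strength, m, ddd)
                            for m in year_months
                        ]
                    )
                )
                nominal = mean_real * deflators.index[year] / 100.0
                quantity = float(
                    rng.lognormal(
                        mean=np.log(config.annual_tablets_per_strength),
                        sigma=config.quantity_sigma,
                    )
                )
                cells.append(
                    PriceCell(year, statin, float(strength), quantity, nominal * quantity)
                )
    return cells


@dataclass(frozen=True)
class GuidelineHistory:
    """Dated national recommendations: (effective month, statin), sorted."""

    events: tuple[tuple[pd.Period, Statin], ...]

    def __post_init__(self):
        events = tuple(
            sorted(((month(m), Statin.parse(s)) for m, s in self.events), key=lambda e: e[0])
        )
        object.__setattr__(self, "events", events)

    def recommended_at(self, when) -> Statin | None:
        m = month(when)
        current = None
        for start, statin in self.events:
            if start <= m:
                current = statin
        return current


def default_guideline_history() -> GuidelineHistory:
    """Simvastatin from the January 2006 appraisal, atorvastatin from the
    May 2014 guideline update."""
    return GuidelineHistory(
        (
            (pd.Period("2006-01", "M"), Statin.SIMVASTATIN),
            (pd.Period("2014-05", "M"), Statin.ATORVASTATIN),
        )
    )


def default_yearly_volumes(
    window: tuple = DEFAULT_WINDOW, scale: float = 1e-3
) -> dict[int, float]:
    """New-patient arrivals per year: 1.15M in 2004 falling linearly to
    0.78M in 2018, scaled to desk size (default 1/1000). Years outside
    2004-2018 clamp to the nearest endpoint."""
    start = month(window[0]).year
    end = month(window[1]).year
    out = {}
    for y in range(start, end + 1):
        yy = min(max(y, 2004), 2018)
        national = 1.15e6 + (0.78e6 - 1.15e6) * (yy - 2004) / (2018 - 2004)
        out[y] = national * scale
    return out


DEFAULT_MODAL_STRENGTHS: Mapping[Statin, float] = {
    Statin.SIMVASTATIN: 40.0,
    Statin.ATORVASTATIN: 20.0,
    Statin.ROSUVASTATIN: 10.0,
    Statin.PRAVASTATIN: 40.0,
    Statin.FLUVASTATIN: 80.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic prescription cohort.

    ``beta`` is the price sensitivity (utility per real GBP/DDD), ``gamma``
    the utility boost of the currently recommended statin, ``sigma`` the
    spread of practice-level preferences. Defaults are the desk-scale study
    conditions: 243 practices, arrivals scaled 1/1000 from the national
    volume trend, window 2003-07 to 2018-12.
    """

    seed: int = 0
    n_practices: int = 243
    window: tuple = DEFAULT_WINDOW
    yearly_volumes: Mapping[int, float] | None = None
    beta: float = 6.0
    gamma: float = 1.5
    sigma: float = 1.0
    discontinuation_hazard: float = 0.04
    switch_probability: float = 0.02
    tablets_per_prescription: int = 28
    modal_strengths: Mapping[Statin, float] = field(
        default_factory=lambda: dict(DEFAULT_MODAL_STRENGTHS)
    )

    def __post_init__(self):
        if not (0 <= self.discontinuation_hazard <= 1):
            raise StatinCostError("discontinuation_hazard must be a probability")
        if not (0 <= self.switch_probability <= 1):
            raise StatinCostError("switch_probability must be a probability")
        if self.sigma < 0:
            raise StatinCostError("sigma must be non-negative")
        if self.beta < 0:
            raise StatinCostError("beta must be non-negative")
        if self.n_practices < 1:
            raise StatinCostError("n_practices must be positive")

    def volumes(self) -> Mapping[int, float]:
        return self.yearly_volumes or default_yearly_volumes(self.window)


def logit_choice_probabilities(utilities: Sequence[float]) -> np.ndarray:
    """Numerically stable softmax; invariant to adding a constant."""
    u = np.asarray(utilities, dtype=float)
    if u.size == 0:
        raise StatinCostError("utilities must be non-empty")
    if not np.all(np.isfinite(u)):
        raise StatinCostError("utilities must be finite")
    z = np.exp(u - u.max())
    return z / z.sum()


def _monthly_covariates(
    months: pd.PeriodIndex,
    prices: Iterable[PriceCell],
    deflators: DeflatorSeries,
    ddd: DddTable,
    guidelines: GuidelineHistory,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-month real price per DDD and recommendation indicator, per statin."""
    cells = list(prices)
    years = sorted({m.year for m in months})
    price_by_year: dict[tuple[Statin, int], float] = {}
    for statin in STATIN_ORDER:
        for year in years:
            try:
                nominal = cost_per_ddd(statin, year, cells, ddd)
            except StatinCostError:
                continue
            price_by_year[(statin, year)] = deflate(nominal, year, deflators)
    P = np.empty((len(months), len(STATIN_ORDER)))
    R = np.zeros((len(months), len(STATIN_ORDER)))
    for t, m in enumerate(months):
        rec = guidelines.recommended_at(m)
        for j, statin in enumerate(STATIN_ORDER):
            key = (statin, m.year)
            if key not in price_by_year:
                raise StatinCostError(
                    f"price series does not cover {statin} in month {m}"
                )
            P[t, j] = price_by_year[key]
            if rec == statin:
                R[t, j] = 1.0
    return P, R


def generate_cohort(
    config: CohortConfig,
    prices: Iterable[PriceCell],
    deflators: DeflatorSeries,
    *,
    guidelines: GuidelineHistory | None = None,
    ddd: DddTable | None = None,
    policy: ComparatorPolicy | None = None,
) -> pd.DataFrame:
    """Simulate a prescription cohort; returns the canonical record frame.

    Byte-identical output for identical inputs and seed. Raises when the
    price series fails to cover any month of the window.
    """
    guidelines = guidelines or default_guideline_history()
    ddd = ddd or DddTable.default()
    policy = policy or ComparatorPolicy()
    months = month_range(*config.window)
    P, R = _monthly_covariates(months, prices, deflators, ddd, guidelines)
    n_s = len(STATIN_ORDER)
    rng = np.random.default_rng(config.seed)

    # practice preferences: sigma * z with z standard normal, so cohorts at
    # different sigma but the same seed are monotone-coupled
    alpha = config.sigma * rng.standard_normal((config.n_practices, n_s))

    volumes = config.volumes()
    lam = np.array(
        [volumes.get(m.year, 0.0) / 12.0 / config.n_practices for m in months]
    )
    arrivals = rng.poisson(lam[None, :].repeat(config.n_practices, axis=0))

    # initial statin per (practice, month, statin) via multinomial-logit
    base_u = -config.beta * P + config.gamma * R  # (T, S)
    counts = np.zeros((config.n_practices, len(months), n_s), dtype=np.int64)
    for p in range(config.n_practices):
        u = base_u + alpha[p][None, :]
        u = u - u.max(axis=1, keepdims=True)
        probs = np.exp(u)
        probs /= probs.sum(axis=1, keepdims=True)
        counts[p] = rng.multinomial(arrivals[p], probs)

    # flatten patients
    p_idx, t_idx, s_idx = np.nonzero(counts)
    reps = counts[p_idx, t_idx, s_idx]
    pat_practice = np.repeat(p_idx, reps)
    pat_start = np.repeat(t_idx, reps)
    pat_statin0 = np.repeat(s_idx, reps)
    n_patients = pat_practice.size

    # persistence: number of monthly prescriptions, truncated at window end
    if config.discontinuation_hazard >= 1.0:
        n_rx = np.ones(n_patients, dtype=np.int64)
    elif config.discontinuation_hazard <= 0.0:
        n_rx = np.full(n_patients, len(months), dtype=np.int64)
    else:
        n_rx = rng.geometric(config.discontinuation_hazard, size=n_patients)
    n_rx = np.minimum(n_rx, len(months) - pat_start)

    total = int(n_rx.sum())
    starts = np.concatenate(([0], np.cumsum(n_rx)))[:-1]
    rec_patient = np.repeat(np.arange(n_patients), n_rx)
    offsets = np.arange(total) - np.repeat(starts, n_rx)
    rec_month_idx = np.repeat(pat_start, n_rx) + offsets

    # monthly switch-to-comparator events (never on the initiation month)
    switch = rng.random(total) < config.switch_probability
    switch &= offsets > 0
    gidx = np.arange(total)
    first_gidx = np.repeat(starts, n_rx)
    marker = np.where(switch, gidx, first_gidx - 1)
    last_switch = np.maximum.accumulate(marker)
    no_switch = last_switch < first_gidx

    cutover_idx = (policy.cutover_month - months[0]).n
    pre_j = STATIN_ORDER.index(policy.pre_comparator)
    post_j = STATIN_ORDER.index(policy.post_comparator)
    comp_at = np.where(rec_month_idx < cutover_idx, pre_j, post_j)
    switched_statin = comp_at[np.clip(last_switch, 0, total - 1)]
    statin_j = np.where(no_switch, np.repeat(pat_statin0, n_rx), switched_statin)

    statin_names = np.array([str(s) for s in STATIN_ORDER])
    modal = np.array([float(config.modal_strengths[s]) for s in STATIN_ORDER])
    frame = pd.DataFrame(
        {
            "patient_id": np.char.add("p", np.char.zfill(rec_patient.astype(str), 7)),
            "practice_id": np.char.add(
                "gp", np.char.zfill(np.repeat(pat_practice, n_rx).astype(str), 4)
            ),
            "issue_month": months[rec_month_idx],
            "statin": statin_names[statin_j],
            "strength_mg": modal[statin_j],
            "tablets": config.tablets_per_prescription,
            "days_supplied": 28,
            "first_episode": offsets == 0,
        }
    )
    frame = frame.sort_values(["patient_id", "issue_month"], kind="stable").reset_index(
        drop=True
    )
    return frame


def fit_choice_model(
    records: pd.DataFrame,
    prices: Iterable[PriceCell],
    deflators: DeflatorSeries,
    *,
    guidelines: GuidelineHistory | None = None,
    ddd: DddTable | None = None,
) -> tuple[float, float]:
    """Maximum-likelihood refit of (beta, gamma) from initiation choices.

    A conditional-logit on the monthly alternative-level covariates (real
    price per DDD and the recommendation indicator), assuming no practice
    effects; used as a parameter-recovery diagnostic for the generator.
    """
    from .domain import records_to_frame

    guidelines = guidelines or default_guideline_history()
    ddd = ddd or DddTable.default()
    frame = records_to_frame(records)
    fe = frame[frame["first_episode"].astype(bool)]
    if fe.empty:
        raise StatinCostError("no initiations to fit")
    months_idx = pd.PeriodIndex(fe["issue_month"], freq="M")
    months = pd.period_range(months_idx.min(), months_idx.max(), freq="M")
    P, R = _monthly_covariates(months, prices, deflators, ddd, guidelines)
    pos = {m: t for t, m in enumerate(months)}
    s_pos = {str(s): j for j, s in enumerate(STATIN_ORDER)}
    counts = np.zeros((len(months), len(STATIN_ORDER)))
    for m, s in zip(months_idx, fe["statin"]):
        counts[pos[m], s_pos[str(s)]] += 1

    def nll(theta):
        beta, gamma = theta
        u = -beta * P + gamma * R
        u = u - u.max(axis=1, keepdims=True)
        logz = np.log(np.exp(u).sum(axis=1, keepdims=True))
        return -np.sum(counts * (u - logz))

    res = optimize.minimize(nll, x0=np.array([1.0, 0.0]), method="BFGS")
    if not res.success and not np.all(np.isfinite(res.x)):
        raise StatinCostError(f"choice-model fit failed: {res.message}")
    return float(res.x[0]), float(res.x[1])
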