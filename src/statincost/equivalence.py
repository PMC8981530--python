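"""LDL-reduction intensity banding and therapeutic dose substitution.

Statin doses are compared by the percentage reduction in LDL cholesterol
they achieve. Doses are grouped into three intensity bands:

* low      — reduction in [20, 30] %
* medium   — reduction in (30, 40] %
* high     — reduction above 40 %

A prescription is substituted onto the comparator statin by picking the
smallest comparator dose in the same intensity band; if the comparator has
no dose in that band, the smallest dose achieving at least the source
reduction; failing that, the largest catalogued comparator dose (flagged as
band-unmatched). Substitution never touches tablet count or duration — it
swaps agent and strength only.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .domain import ComparatorPolicy, Statin, month
from .errors import EquivalenceLookupError, OutOfBandError, StatinCostError

__all__ = [
    "IntensityBand",
    "intensity_band",
    "EquivalenceTable",
    "ldl_reduction",
    "Substitution",
    "substitute",
    "equivalent_dose",
    "comparator_for",
]

LOW_MIN = 20.0
LOW_MAX = 30.0
MEDIUM_MAX = 40.0


class IntensityBand(enum.StrEnum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


def intensity_band(reduction_pct: float) -> IntensityBand:
    """Band of an LDL reduction percentage; boundaries 30 -> low, 40 -> medium."""
    if reduction_pct < LOW_MIN:
        raise OutOfBandError(
            f"LDL reduction {reduction_pct}% is below the lowest intensity band (>= {LOW_MIN}%)"
        )
    if reduction_pct <= LOW_MAX:
        return IntensityBand.LOW
    if reduction_pct <= MEDIUM_MAX:
        return IntensityBand.MEDIUM
    return IntensityBand.HIGH


@dataclass(frozen=True)
class EquivalenceTable:
    """Rows (statin, dose mg) -> % LDL reduction.

    Within one statin the reduction must be non-decreasing in dose, and
    every row must fall in some band (reduction >= 20%).
    """

    reductions: Mapping[tuple[Statin, float], float]

    def __post_init__(self):
        clean: dict[tuple[Statin, float], float] = {}
        for (s, d), pct in self.reductions.items():
            s = Statin.parse(s)
            d = float(d)
            if d <= 0:
                raise StatinCostError(f"dose must be positive, got {d} for {s}")
            pct = float(pct)
            if pct < LOW_MIN:
                raise StatinCostError(
                    f"{s} {d} mg: reduction {pct}% maps to no intensity band (< {LOW_MIN}%)"
                )
            clean[(s, d)] = pct
        for s in {k[0] for k in clean}:
            doses = sorted(d for (t, d) in clean if t == s)
            pcts = [clean[(s, d)] for d in doses]
            if any(b < a for a, b in zip(pcts, pcts[1:])):
                raise StatinCostError(f"{s}: LDL reduction must be non-decreasing in dose")
        object.__setattr__(self, "reductions", clean)

    def doses(self, statin: Statin) -> list[float]:
        s = Statin.parse(statin)
        return sorted(d for (t, d) in self.reductions if t == s)

    def reduction(self, statin: Statin, dose_mg: float) -> float:
        key = (Statin.parse(statin), float(dose_mg))
        try:
            return self.reductions[key]
        except KeyError:
            raise EquivalenceLookupError(
                f"no equivalence row for {key[0]} {key[1]} mg"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.reductions.items(), key=lambda kv: (str(kv[0][0]), kv[0][1]))
        return pd.DataFrame(
            {
                "statin": [str(s) for (s, _), _ in rows],
                "dose_mg": [d for (_, d), _ in rows],
                "ldl_reduction_pct": [p for _, p in rows],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EquivalenceTable":
        return cls(
            {
                (Statin.parse(r.statin), float(r.dose_mg)): float(r.ldl_reduction_pct)
                for r in frame.itertuples(index=False)
            }
        )

    @classmethod
    def default(cls) -> "EquivalenceTable":
        """The shipped default table.

        This is a synthetic default assembled from LDL-reduction figures
        commonly cited in the statin dose-comparison literature; it is a
        reasonable analysis default, not a clinical reference, and every
        correctness test in the package uses small hand-built tables
        instead.
        """
        return _default_table()


@lru_cache(maxsize=1)
def _default_table() -> EquivalenceTable:
    path = resources.files("statincost.data") / "ldl_equivalence_synthetic_default.csv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p)
    return EquivalenceTable.from_frame(frame)


def ldl_reduction(statin: Statin, dose_mg: float, table: EquivalenceTable) -> float:
    """Tabulated % LDL reduction for a (statin, dose)."""
    return table.reduction(statin, dose_mg)


@dataclass(frozen=True)
class Substitution:
    """Result of a dose-equivalence substitution.

    ``band_matched`` is True when the chosen dose sits in the same intensity
    band as the source (always true for the identity substitution).
    """

    statin: Statin
    dose_mg: float
    band_matched: bool


def substitute(
    statin: Statin, dose_mg: float, target: Statin, table: EquivalenceTable
) -> Substitution:
    """Therapeutically similar dose of ``target`` for (statin, dose).

    Smallest same-band target dose; else smallest target dose with at least
    the source reduction; else the largest catalogued target dose, flagged
    band-unmatched. Records already on the target keep their dose.
    """
    statin = Statin.parse(statin)
    target = Statin.parse(target)
    if statin == target:
        # identity short-circuit: a record already on the target is untouched
        return Substitution(target, float(dose_mg), True)
    red = table.reduction(statin, dose_mg)
    band = intensity_band(red)
    candidates = table.doses(target)
    if not candidates:
        raise EquivalenceLookupError(f"target {target} has no catalogued doses")
    same_band = [d for d in candidates if intensity_band(table.reduction(target, d)) == band]
    if same_band:
        return Substitution(target, min(same_band), True)
    at_least = [d for d in candidates if table.reduction(target, d) >= red]
    if at_least:
        return Substitution(target, min(at_least), False)
    return Substitution(target, max(candidates), False)


def equivalent_dose(
    statin: Statin, dose_mg: float, target: Statin, table: EquivalenceTable
) -> float:
    """Dose (mg) of ``target`` therapeutically similar to (statin, dose)."""
    return substitute(statin, dose_mg, target, table).dose_mg


def comparator_for(when: object, policy: ComparatorPolicy | None = None) -> Statin:
    """Policy comparator at a calendar month: a step function with one jump.

    Months strictly before the cutover map to the pre comparator; the
    cutover month itself and all later months map to the post comparator.
    """
    policy = policy or ComparatorPolicy()
    m = month(when)
    return policy.pre_comparator if m < policy.cutover_month else policy.post_comparator
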