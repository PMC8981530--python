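"""Independent brute-force oracle for the savings scenarios.

Everything here is computed per record with plain Python loops and dicts:
no grouping logic, no vectorisation, and its own re-derivation of the
intensity-band substitution rule. It exists only to cross-check the
package and must stay independent of its internals.
"""
from __future__ import annotations


def oracle_band(pct: float) -> str:
    assert pct >= 20
    if pct <= 30:
        return "low"
    if pct <= 40:
        return "medium"
    return "high"


def oracle_equivalent_dose(rows: dict, statin: str, dose: float, target: str) -> float:
    """rows: {(statin_str, dose_mg): reduction_pct}."""
    if statin == target:
        return dose
    red = rows[(statin, dose)]
    band = oracle_band(red)
    candidates = sorted(d for (s, d) in rows if s == target)
    same = [d for d in candidates if oracle_band(rows[(target, d)]) == band]
    if same:
        return same[0]
    at_least = [d for d in candidates if rows[(target, d)] >= red]
    if at_least:
        return at_least[0]
    return candidates[-1]


def oracle_scenarios(
    records,
    cells,
    eq_rows: dict,
    deflator_index: dict,
    cutover=(2012, 5),
    pre="simvastatin",
    post="atorvastatin",
):
    """Per-year (n, actual, hypothetical) for both scenarios.

    Returns {"first": {year: (n, actual, hyp)}, "all": {...}} where the
    all-patients n is the count of distinct patients that year.
    """
    unit = {}
    for c in cells:
        unit[(str(c.statin), float(c.strength_mg), int(c.year))] = (
            c.total_spend / c.total_quantity
        )
    first: dict[int, list] = {}
    allp: dict[int, list] = {}
    patients: dict[int, set] = {}
    for r in records:
        y = r.issue_month.year
        m = r.issue_month.month
        defl = 100.0 / deflator_index[y]
        comp = pre if (y, m) < cutover else post
        statin = str(r.statin)
        strength = float(r.strength_mg)
        if statin == comp:
            sub_s, sub_d = statin, strength
        else:
            sub_s = comp
            sub_d = oracle_equivalent_dose(eq_rows, statin, strength, comp)

        def cost(cap, s, d):
            frac = 1.0 if cap is None else min(r.days_supplied, cap) / r.days_supplied
            return r.tablets * frac * unit[(s, d, y)] * defl

        if r.first_episode:
            a = cost(28, statin, strength)
            h = cost(28, sub_s, sub_d)
            acc = first.setdefault(y, [0, 0.0, 0.0])
            acc[0] += 1
            acc[1] += a
            acc[2] += h
        a = cost(None, statin, strength)
        h = cost(None, sub_s, sub_d)
        acc = allp.setdefault(y, [0, 0.0, 0.0])
        acc[1] += a
        acc[2] += h
        patients.setdefault(y, set()).add(r.patient_id)
    for y, pats in patients.items():
        allp[y][0] = len(pats)
    return {
        "first": {y: tuple(v) for y, v in first.items()},
        "all": {y: tuple(v) for y, v in allp.items()},
    }
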