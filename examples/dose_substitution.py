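"""Therapeutic dose substitution onto the policy comparator.

Every statin dose maps to a percentage LDL-cholesterol reduction, which
places it in a low / medium / high intensity band. A prescription is
substituted by the smallest comparator dose in the same band. The
comparator is simvastatin before May 2012 and atorvastatin afterwards.
"""
import statincost as sc

table = sc.EquivalenceTable.default()

for statin, dose in [
    (sc.Statin.ROSUVASTATIN, 10.0),
    (sc.Statin.ATORVASTATIN, 40.0),
    (sc.Statin.PRAVASTATIN, 20.0),
]:
    pct = sc.ldl_reduction(statin, dose, table)
    band = sc.intensity_band(pct)
    for when in ("2010-01", "2015-01"):
        comp = sc.comparator_for(when)
        sub = sc.substitute(statin, dose, comp, table)
        flag = "" if sub.band_matched else "  (band unmatched)"
        print(
            f"{statin} {dose:g} mg ({pct:g}% LDL, {band}) in {when} "
            f"-> {sub.statin} {sub.dose_mg:g} mg{flag}"
        )
    print()

print("Doses substitute within their intensity band; when the comparator has")
print("no dose in the band, the nearest adequate dose is used and flagged.")
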