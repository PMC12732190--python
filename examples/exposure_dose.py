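"""Exposure-dose arithmetic for food-safety assessment.

Dose = active-lectin concentration (mg/g dry weight) x dry mass consumed
(g).  Four raw kidney seeds (2.44 g dry) at 223.06 mg/g carry ~544 mg of
active lectin — the amount associated with acute food poisoning — while an
entire can of commercially cooked beans (94 g dry matter) at 0.0049 mg/g
carries ~0.46 mg, about three orders of magnitude less.
"""

from hemaquant import exposure_dose, pha_conc_hemagglutination, reduction_ratio
from hemaquant import DilutionSeries

raw = exposure_dose(223.06, 2.44)
print(f"4 raw seeds : {raw.conc_mg_per_g} mg/g x {raw.dry_mass_g} g = {raw.dose_mg:.1f} mg")

titer_based = pha_conc_hemagglutination(
    DilutionSeries.from_w_over_v(10.0, n_wells=24), first_negative=15
)
t = exposure_dose(round(titer_based.conc_mg_per_g, 1), 2.44)
print(f"titer-based : {t.conc_mg_per_g} mg/g x {t.dry_mass_g} g = {t.dose_mg:.0f} mg")

can = exposure_dose(0.0049, 94.0)
print(f"whole can   : {can.conc_mg_per_g} mg/g x {can.dry_mass_g} g = {can.dose_mg:.2f} mg")
print(f"margin      : {raw.dose_mg / can.dose_mg:.0f}-fold below the poisoning-associated dose")
print(f"canned/raw  : {reduction_ratio(0.0049, 223.06):.4f}% of the raw concentration")
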