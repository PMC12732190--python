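"""Serial-dilution mass bookkeeping and HAU titers.

A two-fold serial dilution with 100 µL retained per well puts
start_conc * 100 / 2**(n-1) ng of analyte in well n.  For a purified
positive control at 1.04 mg/mL, well 10 holds ~203 ng, and an endpoint at
well 10 corresponds to a titer of 512 HAU (the reciprocal of the 1:512
dilution).  For a 10% w/v bean-powder extract the same arithmetic tracks
*powder* mass per well.
"""

from hemaquant import DilutionSeries, amount_in_well, hau_from_well

control = DilutionSeries(start_conc_ng_per_ul=1040.0, n_wells=12)
print("purified control, 1.04 mg/mL:")
for n in (1, 8, 9, 10, 11, 12):
    print(f"  well {n:2d}: {amount_in_well(control, n):10.1f} ng")
print(f"  endpoint at well 10 -> titer {hau_from_well(10):g} HAU")

powder = DilutionSeries.from_w_over_v(10.0, n_wells=24)
print("\n10% w/v powder extract (powder mass per well):")
for n in (13, 14, 15, 16):
    print(f"  well {n:2d}: {amount_in_well(powder, n):10.1f} ng powder")
print(f"  endpoint at well 14 -> titer {hau_from_well(14):g} HAU")
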