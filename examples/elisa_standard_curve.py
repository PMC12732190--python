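"""ELISA standard-curve fitting and sample quantitation.

Standards at 0-300 ng are fit by ordinary least squares (replicates enter
individually); a sample absorbance near 1.0 at a 1:8192 dilution of a 10%
w/v extract back-calculates to a concentration in mg active lectin per g
dry powder.  Amounts below the 15 ng LLOQ are censored, not reported as
numbers.
"""

import numpy as np

from hemaquant import elisa_conc, fit_standard_curve

rng = np.random.default_rng(1)
amounts = np.repeat([0.0, 12.5, 25.0, 50.0, 100.0, 200.0, 300.0], 3)
absorbances = 0.0039 * amounts + rng.normal(0.0, 0.01, amounts.size)

curve = fit_standard_curve(amounts, absorbances)
print(
    f"slope {curve.slope_au_per_ng:.4f} AU/ng "
    f"(95% CI {curve.slope_ci95[0]:.4f}-{curve.slope_ci95[1]:.4f}), "
    f"intercept {curve.intercept_au:.4f} AU, r^2 {curve.r2:.4f}"
)

res = elisa_conc(1.0, curve, dilution_factor=8192.0)
print(f"sample at 1:8192, A=1.0 -> {res.ng_in_well:.1f} ng/well "
      f"-> {res.conc_mg_per_g:.1f} mg/g dry powder (flags: {res.flags or 'none'})")

blank = elisa_conc(0.01, curve, dilution_factor=1.0)
print(f"near-blank absorbance -> censored below LLOQ: {blank.censored_below_lloq}")
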