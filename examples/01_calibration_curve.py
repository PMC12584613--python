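"""Build a sulfate calibration curve from synthetic interface spectra.

Simulates a 25-75 mmol/L sodium-sulfate dilution series measured at the
gas-solid interface under 0.3 MPa N2, runs the full processing chain
(despike -> baseline -> Gaussian fit -> area ratio) and regresses the
sulfate-to-N2 peak-area ratio on concentration.  The generator builds
the series so the true line is ratio = 0.01802*C - 0.04239; the printed
slope/intercept show how well the pipeline recovers it from noisy
spectra.
"""

import ramanquant as rq
from ramanquant.synthetic import NOISE_SD_MID

concs = [25.0, 37.5, 50.0, 62.5, 75.0]
series = rq.simulate_calibration_series(concs, replicates=3,
                                        noise_sd=NOISE_SD_MID, seed=42)

points = []
for conc, spectrum in series:
    despiked, spikes = rq.remove_cosmic_rays(spectrum)
    corrected = rq.correct_baseline(despiked).corrected
    ratio = rq.compute_ratio(corrected)
    points.append((conc, ratio))

model = rq.fit_calibration(points)
print(f"fitted calibration line : ratio = {model.slope:.5f} * C {model.intercept:+.5f}")
print(f"coefficient of determination R^2 = {model.r_squared:.5f}")
print(f"validity range          : {model.conc_range[0]:.0f}-{model.conc_range[1]:.0f} mmol/L")
print()
print("The slope absorbs the sulfate/N2 quantification-factor ratio and the")
print("fixed N2 amount; an unknown spectrum's ratio is converted to mmol/L")
print("by inverting this line (see 02_quantify_unknown.py).")
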