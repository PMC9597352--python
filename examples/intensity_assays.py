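"""Scalar intensity assays: pH calibration, CTCF, degradation, fold change.

Fits a ratiometric pH calibration line (dual-excitation 340/380 ratio in
clamped buffers, pH 4-6), inverts a measured ratio to a lysosomal pH,
evaluates corrected total cell fluorescence, and normalizes a pulse-chase
degradation time course.
"""

import numpy as np

from vesiquant import (
    CtcfInput,
    ctcf,
    degradation_fractions,
    fit_ph_calibration,
    fold_change,
    ph_from_ratio,
    synth_calibration_readings,
    synth_decay_timecourse,
)

# --- ratiometric pH ---------------------------------------------------------
readings = synth_calibration_readings(
    slope=-0.62, intercept=4.5, ph_values=np.linspace(4, 6, 7), noise_sd=0.01, seed=1
)
curve = fit_ph_calibration(readings)
print(
    f"calibration: ratio = {curve.slope:.4f} * pH + {curve.intercept:.4f} "
    f"(residual SE {curve.residual_se:.4f}, n = {curve.n_points})"
)
measured_ratio = 1.04
est = ph_from_ratio(curve, measured_ratio)
flag = "" if est.in_range else "  [outside calibration range]"
print(f"ratio {measured_ratio} -> pH {est.ph:.2f}{flag}")

# --- corrected total cell fluorescence --------------------------------------
value = ctcf(CtcfInput(integrated_density=1000.0, cell_area=10.0, background_mean=5.0))
print(f"\nCTCF(1000, 10 px, 5/px) = {value:.0f}  (integrated density minus area x background)")

# --- pulse-chase degradation ------------------------------------------------
tc = synth_decay_timecourse(initial=120.0, half_life_min=30.0, times_min=[0, 15, 30, 45, 60])
print("\nresidual receptor fraction vs chase time (half-life 30 min):")
for t, frac in degradation_fractions(tc):
    print(f"  t = {t:4.0f} min: {100 * frac:5.1f} % of pulse")

# --- fold change ------------------------------------------------------------
print(f"\nfold change (treated mean 15.3 vs control 10.2): {fold_change(15.3, 10.2):.2f}x")
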