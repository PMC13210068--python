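"""Reduce shake-flask UV measurements to mole-fraction solubility.

Builds a small replicate table for a vanillic-acid-like solute in a binary
organic/water mixture, inverts the calibration line, applies the
density-based mole-fraction conversion and prints per-composition means.
"""

import pandas as pd

from dooit2 import CalibrationCurve, MolarMasses, fit_calibration, lod_loq
from dooit2.units import reduce_measurements

# calibration from standards (concentration mg/mL, absorbance)
points = [(0.001, 0.007), (0.005, 0.141), (0.01, 0.308), (0.02, 0.643), (0.04, 1.313)]
curve = fit_calibration(points)
print(f"calibration: A = {curve.slope:.4f} C + {curve.intercept:.4f}  (R2 = {curve.r_squared:.4f})")

lod, loq = lod_loq(sigma_blank=0.001, slope=curve.slope)
print(f"LOD = {lod:.5f} mg/mL, LOQ = {loq:.5f} mg/mL (ratio fixed at 10/3.3)")

# triplicate saturated-solution measurements at two solvent compositions
replicates = pd.DataFrame(
    {
        "x_cosolvent_prime": [0.3, 0.3, 0.3, 0.7, 0.7, 0.7],
        "absorbance": [0.52, 0.55, 0.50, 1.21, 1.19, 1.25],
        "density_g_per_ml": [1.02, 1.02, 1.01, 1.05, 1.06, 1.05],
    }
)
masses = MolarMasses(m_solute=168.15, m_solvent_a=115.13, m_solvent_b=18.015)
out = reduce_measurements(replicates, masses, calibration=curve)
print(out.to_string(index=False))
print(
    "x_mean is the mole-fraction solubility at each solute-free composition;"
    " x_sd is the replicate scatter."
)
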