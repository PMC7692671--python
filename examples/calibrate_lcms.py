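"""Standard-curve calibration and PT-density arithmetic.

Fits the dinucleotide standard curve (peak-area ratio to the Sp internal
standard vs concentration over the 0-200 fmol/uL ladder), inverts it for a
measured sample, and converts hydrolysate mole quantities into PT per
million nucleotides using base-pairing (total nt = 2*(C+T)).
"""

import numpy as np

from ptseq import (CalibrationPoint, HydrolysateQuant, fit_calibration,
                   invert_calibration, pt_density)

rng = np.random.default_rng(0)
ladder = [0, 2, 10, 20, 40, 100, 200]  # fmol/uL, Rp standard
points = [CalibrationPoint(c, 0.0125 * c + 0.004 + rng.normal(0, 0.01))
          for c in ladder]
curve = fit_calibration(points)
print(f"GpsA curve: response = {curve.slope:.5f} x conc + "
      f"{curve.intercept:.5f}  (r^2 = {curve.r_squared:.4f})")

measured_ratio = 0.52  # sample peak-area ratio to the internal standard
conc = invert_calibration(curve, measured_ratio)
print(f"measured ratio {measured_ratio} -> {conc:.1f} fmol/uL GpsA")

quant = HydrolysateQuant(mol_c=0.25, mol_t=0.25,
                         mol_gpsa=3.25e-4, mol_gpst=3.61e-4)
densities = pt_density(quant)
print(f"PT density: GpsA {densities['GpsA']:.0f} per 1e6 nt, "
      f"GpsT {densities['GpsT']:.0f} per 1e6 nt")
# The density divides each PT dinucleotide quantity by total nucleotides
# 2*(C+T); it is invariant to the absolute amount of DNA hydrolysed.
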