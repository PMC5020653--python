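"""Two-state wrapping model: threshold, linker efficiency, wrapped fraction.

For a 1 um particle (R = 0.5 um) on a floppy DOPC membrane
(kappa = 21 kBT, sigma ~ 0) the wrapping threshold is an adhesion energy
per area of 2 kappa / R^2 = 168 kBT/um^2.  Comparing with the avidin-biotin
bond energy (17 kBT) at the measured critical linker density
(513 linkers/um^2) says only ~2% of surface linkers actually bind.
The wrapped fraction vs linker density is a two-state Boltzmann occupancy,
smoothed by the +-77 um^-2 batch-to-batch spread in linker density.
"""

import numpy as np

from memcurv import WrappingModelParams, linker_efficiency, threshold_adhesion, wrapped_fraction_curve

thr = threshold_adhesion(kappa=21.0, R=0.5)
eff = linker_efficiency(thr, bond_energy=17.0, critical_density=513.0)
print(f"zero-tension wrapping threshold: {thr:.1f} kBT/um^2")
print(f"effective linker binding efficiency: {eff * 100:.2f} % (~2 %)")

params = WrappingModelParams(binding_efficiency=eff)
for rho in (200.0, 450.0, 513.0, 600.0, 900.0):
    f_sharp = wrapped_fraction_curve([rho], params)[0]
    f_smooth = wrapped_fraction_curve([rho], params, density_spread=77.0)[0]
    print(f"rho = {rho:6.0f} /um^2   wrapped fraction: sharp {f_sharp:.3f}, "
          f"with density spread {f_smooth:.3f}")
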