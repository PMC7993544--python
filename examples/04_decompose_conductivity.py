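"""Decompose a conductivity map into compartment conductivities.

Uses a uniform slab with vesicle-phantom-like parameters: no neurites,
40% soma volume, beta = 1 (same electrolyte inside and outside). The
compartment conductivities sum back to sigma_H exactly.
"""

import numpy as np

from condecomp import SandiParamMaps, compartment_sigmas, estimate_c_ec

shape = (8, 8, 4)
ones = np.ones(shape)
maps = SandiParamMaps(f_in=0.0 * ones, f_ec=0.6 * ones, D_in=1e-3 * ones,
                      D_ec=1.36e-3 * ones, r_s=6.5e-3 * ones,
                      mask=np.ones(shape, dtype=bool))
sigma_h = 1.0 * ones

conc = estimate_c_ec(sigma_h, maps, beta=1.0, D_is=2e-3)
comps = compartment_sigmas(maps, conc, D_is=2e-3)

v = (0, 0, 0)
print(f"c_ec_bar  {conc.c_ec_bar[v] * 1e-3:.4f}  (per 1e-3 mm^2/s)")
print(f"sigma_ec  {comps.sigma_ec[v]:.4f} S/m")
print(f"sigma_ne  {comps.sigma_ne[v]:.4f} S/m")
print(f"sigma_so  {comps.sigma_so[v]:.4f} S/m")
total = comps.sigma_ec + comps.sigma_ne + comps.sigma_so
print(f"closure |sum - sigma_H| max = {np.max(np.abs(total - sigma_h)):.2e}")
# With f_ec = 0.6 and D_ec = 1.36e-3, roughly half the conductivity is
# extracellular and half resides in the soma compartment; the sum is exact.
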