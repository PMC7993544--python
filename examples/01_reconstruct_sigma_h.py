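"""Reconstruct high-frequency conductivity from a simulated transceive phase.

Builds a two-region phantom (1.0 S/m inclusion in a 0.8 S/m background),
forward-simulates the B1 transceive phase, and solves the stabilized
convection-reaction PDE to recover the conductivity map.
"""

import numpy as np
import scipy.ndimage as ndi

from condecomp import PdeConfig, forward_phase, solve_stabilized_pde, vesicle_phantom

spec = vesicle_phantom(shape=(48, 48, 24), spacing=(2.0, 2.0, 2.0),
                       sigma_bg=0.8, sigma_roi=1.0)
phase = forward_phase(spec)
sigma = solve_stabilized_pde(phase, PdeConfig(c=0.05))

roi_core = ndi.binary_erosion(spec.geometry == 1, iterations=4)
bg_core = ((spec.geometry == 0)
           & ~ndi.binary_dilation(spec.geometry == 1, iterations=4)
           & ndi.binary_erosion(spec.mask, iterations=5))

print(f"ROI mean sigma_H        {sigma.sigma_h[roi_core].mean():.4f} S/m  (true 1.0)")
print(f"background mean sigma_H {sigma.sigma_h[bg_core].mean():.4f} S/m  (true 0.8)")
print(f"linear-solve residual   {sigma.residual:.2e}")
# Region means land within a few percent of the prescribed conductivities;
# voxels near the interface are blurred by the artificial diffusion term.
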