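"""Train the random-forest inverter and recover microstructure parameters.

Builds a reduced training dictionary (7 points per parameter), trains a
forest, then predicts the parameters of a known synthetic voxel from its
direction-averaged shell signals.
"""

import numpy as np

from condecomp import (PulseSequence, SandiParams, build_training_grid, sandi_signal,
                       train_forest)

seq = PulseSequence(delta=6e-3, Delta=53.8e-3)
shells = np.array([1000.0, 2200.0, 3000.0, 3600.0])

grid = build_training_grid(shells, seq, n_per_param=7, seed=0)
model = train_forest(grid, noise_snr=None, n_trees=50, seed=0)
print("per-parameter held-out MSE:", np.array2string(model.test_mse, precision=4))

truth = SandiParams(f_in=0.5, f_ec=0.9, D_in=2.0e-3, D_ec=2.0e-3, r_s=8e-3)
features = sandi_signal(shells, truth, seq)[None, :]
pred = model.predict(features)[0]
names = ("f_in", "f_ec", "D_in", "D_ec", "r_s")
for name, t, p in zip(names, (0.5, 0.9, 2.0e-3, 2.0e-3, 8e-3), pred):
    print(f"{name:>5}: true {t:.4g}  predicted {p:.4g}")
# Extracellular-dominated voxels like this one are well identified from the
# four shells; voxels with balanced pools recover less accurately because
# several parameter combinations produce nearly identical signals.
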