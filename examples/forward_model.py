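"""Predict the cryo-EM density of a toy helix and verify mass conservation.

Builds a 10-residue ideal polyalanine helix, predicts the density at voxels
near the model with the 5-Gaussian forward model, and checks that blurring
with a B-factor lowers the peak while conserving each atom's integrated
density.
"""

import numpy as np
from scipy.integrate import quad

import voxfit as vf
from voxfit.forward import atom_density, predict_map
from voxfit.scattering import load_atomistic_table

table = load_atomistic_table()
model = vf.make_toy_structure("helix", 10, seed=1)

for b in (0.0, 40.0):
    integral, _ = quad(lambda r: 4 * np.pi * r**2 * atom_density(table, "C", b, r),
                       0, 60, limit=300)
    print(f"carbon: b={b:>4.0f} Å²  peak={atom_density(table, 'C', b, 0.0):7.3f}"
          f"  integral={integral:.4f} (Σ A_k = {table.total_weight('C'):.4f})")

bfactors = np.full(10, 30.0)
full, halves, truth = vf.simulate_map([model], [1.0], bfactors, noise_sd=0.0, seed=2)
voxels = vf.select_voxels(full, model)
pred = predict_map(model, bfactors, voxels, table)
print(f"\n{len(voxels)} voxels within 3.5 Å of the model; "
      f"predicted density range [{pred.values.min():.2e}, {pred.values.max():.3f}]")
print("Blurring (larger b) flattens the peak but the per-atom integral is "
      "unchanged — B-factors redistribute density, they do not destroy it.")
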