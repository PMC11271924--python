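"""Fit a single-Gaussian coarse-grained bead to atomistic density.

Scans (A, B) on the published-style grid for a lone carbon atom blurred by a
representative B-factor, and for the backbone bead of a polyalanine helix.
"""

import numpy as np

import voxfit as vf
from voxfit.cgfit import BeadOccurrence, fit_bead_parameters, occurrences_from_model
from voxfit.scattering import load_atomistic_table

table = load_atomistic_table()

carbon = BeadOccurrence(["C"], np.zeros((1, 3)), np.zeros(3))
a, b, mse = fit_bead_parameters([carbon], table, bfactor=40.0)
print(f"carbon bead (blur 40 Å²): A={a:.1f}, B={b:.1f} Å², MSE={mse:.2e}")
print(f"  integrated density {a:.2f} vs atomistic Σ A_k = "
      f"{table.total_weight('C'):.2f} "
      f"({100 * abs(a - table.total_weight('C')) / table.total_weight('C'):.1f}% off)")

model = vf.make_toy_structure("helix", 12, seed=1)
occ = occurrences_from_model(model)
for key, instances in sorted(occ.items()):
    a, b, mse = fit_bead_parameters(instances, table, bfactor=40.0)
    print(f"{key}: A={a:.1f}, B={b:.1f} Å² from {len(instances)} occurrences "
          f"(MSE {mse:.2e})")
print("BB groups four heavy atoms (weight ≈ 9.7), beyond the A grid's cap "
      "of 8.0 — its fit saturates the scan corner by construction.")
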