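"""Atomic environment vectors and a neural-network potential.

Featurizes a benzene-like toy solute, runs it through a randomly
initialized per-species network ensemble, and shows the two invariances
that make AEVs usable as ML inputs: rigid rotations leave the descriptor
unchanged, and the predicted energy is a sum of atomic contributions whose
forces integrate to zero net force.
"""

import numpy as np
from scipy.stats import ortho_group

from hybridmd import AEVSpec, assemble_aev, generate_random_ensemble, generate_toy_solute

solute = generate_toy_solute("ring6")
spec = AEVSpec(elements=("H", "C"))
print(f"AEV length for 2 elements: {spec.aev_length} "
      f"(2 radial blocks x {spec.n_radial} + 3 angular blocks x {spec.n_angular})")

aev = assemble_aev(solute.coordinates, solute.species, 0, spec)
rot = ortho_group.rvs(3, random_state=0)
aev_rot = assemble_aev(solute.coordinates @ rot.T, solute.species, 0, spec)
print(f"rotation invariance error: {np.abs(aev - aev_rot).max():.2e}")

ensemble = generate_random_ensemble(("H", "C"), n_members=8, seed=0)
report, spread = ensemble.predict_with_spread(solute.species,
                                              solute.coordinates)
print(f"ensemble energy: {report.total:.4f} kcal/mol "
      f"(member spread {spread:.4f})")
print(f"net force: {np.abs(report.forces.sum(axis=0)).max():.2e} kcal/mol/A")
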