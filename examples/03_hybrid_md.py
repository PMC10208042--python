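"""Hybrid ML-solute / polarizable-solvent dynamics with a multi-timestep
integrator.

The hybrid energy is V_FF(solute+solvent) + V_ML(solute) - V_FF(solute):
the solvent and the solute-solvent coupling come from the polarizable
force field, the solute's internal surface from the ML model.  The
difference force dV_ML rides on the slow RESPA level, so the ML gradient
is only evaluated at the 1 fs outer step while the stiff bonded terms are
integrated at 0.25 fs.
"""

import numpy as np

from hybridmd import (FFSettings, ForceField, ForceSplit, HybridPotential,
                      IntegratorConfig, bonded_energy_forces,
                      draw_maxwell_boltzmann, ff_mimic_with_noise,
                      generate_toy_solute, partition_system, run_md, solvate)

solute = generate_toy_solute("ring6", seed=0)
system = solvate(solute, 20, seed=0)
partition = partition_system(system, range(solute.n_atoms))
print(f"solute: {partition.n_solute} atoms; "
      f"environment: {partition.environment_indices.size} atoms")

settings = FFSettings(vdw_cutoff=4.2, ewald_real_cutoff=4.2,
                      pol_tolerance=1e-5, neighbor_skin=0.3)
# stand-in for a trained solute model: the force field's own solute surface
# plus a small random network correction, so dV_ML is small but non-zero
model = ff_mimic_with_noise(system.parameters.subset(partition.solute_indices),
                            ("H", "C"), seed=1, scale=0.05,
                            settings=settings)
hp = HybridPotential(ff=ForceField(settings), ml=model, partition=partition)

total = hp.energy_forces
fast = lambda sy: bonded_energy_forces(sy.coordinates, sy.parameters, sy.box)
split = ForceSplit.from_total(total, fast)

draw_maxwell_boltzmann(system, 300.0, np.random.default_rng(0))
config = IntegratorConfig(scheme="respa", dt_inner=0.25, dt_outer=1.0,
                          temperature=300.0, friction=0.01, seed=0)
result = run_md(system, total, config, n_steps=200, stride=20, split=split)
print(f"mean temperature over the run: "
      f"{result.summary['mean_temperature']:.1f} K (target 300 K)")
delta = hp.delta_ml_energy_forces(system)
print(f"final dV_ML = V_ML - V_FF(solute): {delta.total:.3f} kcal/mol "
      f"(small when the two solute surfaces agree)")
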