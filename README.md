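# hybridmd

Hybrid machine-learning / polarizable force-field molecular dynamics at
desk scale.

Condensed-phase simulations of a small molecule benefit from two very
different models at once: a neural-network potential reproduces the
solute's internal quantum-chemical surface, while a polarizable force
field handles the solvent and the long-range electrostatics that local ML
models cannot see. `hybridmd` implements the full machinery of that
coupling as a compact, fully testable Python library for method
development and teaching: every component — descriptors, networks, force
field, integrators, estimators — is exercised end to end on synthetic toy
systems generated from seeds, with no trained models or external data.

## What is inside

* **Descriptors** — atomic environment vectors (AEVs): radial and angular
  symmetry functions with a cosine cutoff `f_c(R) = (cos(πR/R_c)+1)/2`,
  species-blocked layout, analytic Jacobians; plus the sorted
  local-environment descriptor with a neighbor-defined local frame.
* **Neural-network potential** — per-element feed-forward networks mapping
  AEVs to atomic energies, `E = Σ_i E_i(G_i)`, analytic forces through the
  AEV Jacobian, ensembles with mean/spread prediction, lossless JSON/YAML
  serialization.
* **Polarizable force field** — MM3-like anharmonic bonds/angles with
  Urey–Bradley 1–3 terms, Halgren buffered 14–7 van der Waals
  (softcore-ready), charges + point dipoles under direct Ewald summation,
  and Applequist/Thole induced dipoles solved by preconditioned conjugate
  gradient (default tolerance 1e-5).
* **Hybrid potential** — the subtractive partition
  `V_HYB(P∪W) = V_FF(P∪W) + V_ML(P) − V_FF(P)` with the solute P
  covalently isolated, the difference potential
  `ΔV_ML = V_ML(P) − V_FF(P)`, and a divergence monitor that flags
  desynchronization of the two solute surfaces.
* **Integrators** — Velocity Verlet, BAOAB Langevin, and the impulse
  multi-timestep schemes BAOAB-RESPA (bonded / non-bonded + ΔV_ML) and
  BAOAB-RESPA1 (bonded / switched short-range / long-range + ΔV_ML), with
  hydrogen mass repartitioning, the Bussi stochastic-rescaling thermostat
  and a Berendsen barostat.
* **Free energies** — alchemical decoupling (electrostatics annihilated
  first, then softcore vdW) over a λ schedule, Bennett-acceptance-ratio
  estimation with asymptotic and bootstrap errors, one-sided reweighting
  from force-field trajectories onto the hybrid surface, and
  double-decoupling binding free energies.
* **Synthetic systems** — seeded generators for flexible 3-site polarizable
  water boxes, toy solutes (diatomic, benzene-like ring, chains), random
  ML models/ensembles, and an FF-mimic adapter that realizes the exact
  hybrid cancellation identity.

## A worked example

```bash
python examples/01_water_box_forcefield.py
```

prints, for a 32-water toy box (seed 1):

```
96 atoms in a 9.86 A box
  bonded               0.0000 kcal/mol
  vdw                209.4424 kcal/mol
  elec_perm           -3.6959 kcal/mol
  polarization       -25.7373 kcal/mol
  total              180.0092 kcal/mol
net force (should be ~0): 1.39e-13 kcal/mol/A
```

The bonded energy is zero because every water is generated at its
equilibrium internal geometry; the large positive van der Waals energy is
the unrelaxed lattice start (drain it with
`hybridmd.dynamics.minimize` before production runs); the polarization
term is the many-body induced-dipole energy and is always ≤ 0; and the
vanishing net force checks Newton's third law through the Ewald sum.

The other examples build on this: `02_descriptors_and_mlp.py`
(AEV invariances, ensemble prediction), `03_hybrid_md.py` (hybrid
multi-timestep dynamics of a ring solute in water), `04_free_energy.py`
(a 5-window toy decoupling with BAR and bootstrap errors).

A thin CLI mirrors the library:
`hybridmd generate|featurize|md|fep|bar|reweight|info`.

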