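# Methods

This note documents the models implemented in `hybridmd`, the numerical
choices behind them, what the synthetic systems do and do not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Units and constants

Lengths in Å, time in fs, mass in amu, energy in kcal/mol, charge in units
of the elementary charge. `k_B = 0.0019872041` kcal/(mol·K), Coulomb
constant `332.06371` kcal·Å/(mol·e²). Kinetic energies computed in
amu·Å²/fs² are converted with 1 kcal/mol = 4.184e-4 amu·Å²/fs².

## Descriptors and the network potential

The atomic environment vector of atom *i* concatenates, per neighbor
species, radial symmetry functions
`Σ_j exp(−η(R_ij−R_s)²) f_c(R_ij)` and, per unordered species pair,
angular functions
`2^(1−ζ) (1+cos(θ_ijk−θ_s))^ζ exp(−η((R_ij+R_ik)/2−R_s)²) f_c(R_ij) f_c(R_ik)`
with the cosine cutoff `f_c(R) = (cos(πR/R_c)+1)/2`, which is C¹ with
vanishing slope at `R_c`. Defaults: radial cutoff 5.2 Å with 16 shifts in
[0.9, R_c) at η = 16 Å⁻²; angular cutoff 3.5 Å with a 4 × 8 grid of
distance and angle shifts at η = 8, ζ = 32. The radial cutoff follows the
convention of local ML potentials for organic molecules; the angular
cutoff and grid sizes are package defaults, serialized with every model so
a model file is self-describing. Neighbor contributions are accumulated in
a canonical (species, distance) order, which makes the AEV bitwise
invariant under permutation of same-species atoms, not merely invariant to
rounding.

Derivatives of both function families with respect to all involved atom
positions are analytic; the angular part differentiates through
`θ = arccos(û·v̂)` with the cosine clipped away from ±1. Finite
differences are the oracle for every force path in the tests.

Per-element feed-forward networks map AEVs to atomic energies; the default
activation is a CELU-type smooth function (C¹), so forces are continuous.
The total is a plain sum of atomic terms plus per-element shifts, which
gives locality (fragments separated beyond the cutoff decouple exactly)
and extensivity. Ensembles average member energies and forces; the member
spread (population standard deviation) is reported as a cheap uncertainty
signal. Models serialize to JSON or YAML with a schema version; binary
pickle-style formats are deliberately not supported.

The sorted local-environment descriptor (rows `(1/R, x/R², y/R², z/R²)` in
a local frame) builds its frame from the two nearest neighbors — first
axis toward the nearest, second in their plane, third right-handed — with
ties broken by atom index, and sorts rows by species then inverse
distance. Collinear two-neighbor environments have no unique frame and
are rejected.

## Reduced polarizable force field

**Bonded.** Bond stretches `k Δr²(1 + c₃Δr + c₄Δr²)` and angle bends of
the same anharmonic form (Δθ in radians), plus harmonic Urey–Bradley 1–3
distance terms. 1-2 and 1-3 pairs are excluded from all non-bonded
interactions.

**Van der Waals.** Halgren's buffered 14–7 with δ = 0.07, γ = 0.12;
cubic-mean combining for r₀ and HHG combining for ε. Note the buffered
form has `E(r₀) = −ε` exactly while its true minimum lies slightly inside
r₀ — the tests assert the former. A C² quintic switch tapers the
interaction to zero over the last 1 Å below the cutoff (default 12 Å;
small toy boxes use proportionally smaller cutoffs). The alchemical
softcore inflates both buffered denominators by `β(1−λ)²` (β = 0.7) and
scales the term by `λ^t` (t = 5); λ = 1 recovers the plain form exactly
and the energy remains finite at r = 0 for λ < 1.

**Electrostatics.** Point charges and lab-frame point dipoles under direct
Ewald summation: erfc-screened real-space kernels (B₀…B₃ recursions),
explicit half-space k-sum with `S(k) = Σ_j (q_j + i k·d_j) e^{ik·r_j}`,
charge and dipole self terms, tinfoil boundary, and the uniform-background
correction `−πQ²/(2α²V)` for net-charged boxes. `EwaldSettings.auto`
chooses α and the integer k-shell so both truncation errors sit at a
requested accuracy. Permanent multipoles stop at dipoles (no
quadrupoles); because stored dipoles are fixed in the lab frame they
cannot exert torques, so the toy water model carries its permanent
anisotropy in its three point charges and keeps permanent dipoles at zero.
Fixed-frame dipoles remain supported (and force-tested) for non-rotating
validation systems.

**Polarization.** Isotropic site polarizabilities with Thole exponential
damping (`λ₃ = 1 − e^{−a u³}`, `λ₅ = 1 − (1+a u³)e^{−a u³}`,
`u = r/(α_i α_j)^{1/6}`, a = 0.39) applied to every interaction involving
an induced dipole. The induced dipoles minimize the variational functional
`U(μ) = ½ μᵀ(α⁻¹ − T)μ − μᵀE_perm`, solved by conjugate gradient with the
diagonal-α preconditioner to an absolute residual 2-norm of 1e-5 by
default. Each molecule acts as one polarization group: excluded (1-2/1-3)
pairs contribute neither permanent interactions nor permanent field, but
mutual induction couples all pairs. Forces use the converged-variational
(envelope) expression; at the default 1e-5 tolerance this leaves a small
non-conservative residue, so force-accuracy tests tighten the solver to
1e-8 (where agreement with finite differences reaches ~1e-4 relative or
better, limited by the solve itself).

By default the *mutual* induced–induced coupling is restricted to the
real-space screened tensor — every CG iteration then avoids k-space work —
while the permanent field driving the induction always gets the full Ewald
treatment. The restriction makes the polarization energy weakly dependent
on the Ewald splitting parameter; `full_mutual_ewald=True` restores the
complete (α-independent) coupling and is what the Ewald-correctness tests
use. Both modes are variationally consistent, so forces match finite
differences in either.

## Hybrid partition

`V_HYB(P∪W) = V_FF(P∪W) + V_ML(P) − V_FF(P)`: a mechanical (subtractive)
embedding. The ML model sees only solute atoms; the subtracted solute
force field is evaluated non-periodically on the isolated solute, with
polarization self-consistency included in both solute terms. Bonded terms
crossing the solute/environment boundary are rejected at partition time.
With the FF-mimic adapter (an object satisfying the ML interface that
evaluates exactly the isolated-solute force field) the hybrid collapses
algebraically to the pure force field; this identity, which holds bitwise
when both paths start the dipole solve from zero, is the central
correctness anchor of the coupling code. When the solute is the whole
system the hybrid short-circuits to the pure ML energy.

Alchemical scaling acts only inside `V_FF(P∪W)`: λ_ele multiplies the
solute charges, permanent dipoles and polarizabilities (annihilation,
intramolecular terms included — the standard protocol when the solute's
internal surface is carried by the λ-independent ML term), and λ_vdw
drives the softcore on solute–environment pairs only. `V_ML(P)` and
`V_FF(P)` are λ-independent by construction.

`ΔV_ML = V_ML(P) − V_FF(P)` carries forces on solute atoms only. The
divergence monitor compares the trailing-window mean of |ΔV_ML| with the
initial window; drift beyond a threshold (default 5 kcal/mol) recommends a
halt — the situation a reactive ML surface creates when the force-field
topology can no longer follow.

## Integrators

BAOAB splits Langevin dynamics as B(dt/2) A(dt/2) O(dt) A(dt/2) B(dt/2)
with the exact Ornstein–Uhlenbeck O-step; γ = 0 reduces it to Velocity
Verlet exactly. The multi-timestep schemes are impulse (RESPA) methods
with the O-step at the innermost level: slow forces kick for dt_outer/2,
the fast (bonded) forces propagate with BAOAB at dt_inner, and RESPA1
inserts a mid level carrying switched short-range non-bonded forces
(vdW + screened charge–charge, C² switch centered at a configurable
distance, 1 Å width). ΔV_ML always rides the outermost level, which is
the point of the hybrid splitting: the ML gradient is evaluated once per
outer step. The slow level is defined by subtraction from the full
potential, so fast + mid + slow equals the full force identically.

Hydrogen mass repartitioning multiplies H masses by a configurable factor
(default 3) and subtracts the added mass from the unique bonded heavy
atom, conserving total mass exactly.

The Bussi thermostat implements canonical stochastic velocity rescaling;
the Berendsen barostat scales box and coordinates isotropically with the
per-step factor clamped to [0.9, 1.1]. The instantaneous pressure comes
from the kinetic term plus a central finite difference of the potential
under isotropic scaling — numerically exact for any implemented potential
and much simpler than hand-deriving the Ewald reciprocal virial; the
barostat is never applied on inner substeps. Stochastic integrators draw
from a Philox counter-based generator keyed by the run seed, so
trajectories are bitwise reproducible.

`minimize` (L-BFGS on the analytic forces) exists because the lattice
generator intentionally produces unrelaxed configurations; draining that
potential energy before thermostatted runs is part of the standard
protocol here.

## Free energies

The default λ schedule decouples electrostatics first (λ_ele 1→0 at
λ_vdw = 1) and then the softcore vdW (λ_vdw 1→0), 21 windows by default
split 11 + 11 around the shared (0, 1) midpoint, uniform per segment.
Windows are sampled sequentially (each starts from its predecessor's final
configuration after re-equilibration); at each stored sample the
λ-dependent full-system FF energy is cross-evaluated at the neighboring
windows — the ML and isolated-solute terms cancel in every window-to-window
difference, so no ML evaluations enter the work values.

BAR solves the Bennett self-consistent equation by bracketed root finding
(1e-8 kcal/mol) with overflow-safe logistic weights; errors come from
Bennett's asymptotic variance and from a seeded bootstrap over both sample
directions. Degenerate overlap is reported as an infinite error, never a
silent number. The one-sided exponential (Zwanzig) estimator is used only
for the surface-change terms of the reweighting fallback, with an
effective-sample-size diagnostic; windows with ESS below 10 are flagged.

Reweighting runs the windows on the pure-FF surface (hybrid with the
FF-mimic, so no ML gradients), chains BAR there, and corrects each
window by the FF→hybrid surface-change free energies at its end states:
`ΔG_hyb(w) = ΔG_FF(w) − ΔG_surf(λ_w) + ΔG_surf(λ_{w+1})`. The
surface-change observable is exactly ΔV_ML, which is λ-independent, so
intermediate corrections telescope and only the end states survive in the
total. Binding free energies combine two decoupling legs,
`ΔG_bind = ΔG_decouple(solution) − ΔG_decouple(complex)`, errors in
quadrature; no standard-state or restraint corrections are applied.

## Synthetic systems

The toy water is a 3-site flexible model: charges −0.51966/+0.25983 e,
polarizabilities 0.837/0.496 ų with Thole a = 0.39, anharmonic O–H
stretch (r₀ = 0.9572 Å, k = 450, MM3-like cubic/quartic), harmonic bend
(104.52°, 55 kcal/mol/rad²) with a Urey–Bradley H–H term, and buffered
14–7 sites on O and H. It is deliberately *not* a fitted water model: it
exercises every term the force field implements at realistic magnitudes.
Boxes are jittered lattices with random molecular orientations and an
O–O clash guard (≥ 2.4 Å); the default density matches ambient water.
Random ML models draw layer weights from scaled normals and calibrate the
output layer so per-atom energies stay below 10 kcal/mol on probe AEVs,
keeping toy MD stable. Everything is bitwise deterministic under its
seed.

What passing tests show, and what they do not: the synthetic systems
validate the *machinery* — identities, gradients, estimators, integrator
limits and stability — at realistic sizes of every quantity. They say
nothing about chemical accuracy against experiment, which would require
trained networks and fitted force-field parameters.

## Problem sizes and tolerances used by the shipped runs

Test and acceptance runs use desk-scale sizes chosen as part of the
package's design: 64-water boxes (12.4 Å edge) with 5.8 Å cutoffs for
integrator checks; ~1.5 ps multi-timestep stability runs (first half
discarded, block-averaged standard errors); 0.4–0.6 ps NVE drift checks at
0.2 fs with drift measured between block-averaged total energies over the
first and last thirds of the run (the instantaneous Verlet ripple at this
step size is larger than the secular drift and is not the
conserved-quantity statistic of interest); 21-window
toy decouplings with tens of steps per window. BAR oracles run at 1e5
samples where closed forms exist. The Ewald accuracy default is 1e-8
(1e-6 in MD runs), polarization tolerance 1e-5 (1e-6 in energy-conservation runs, where the
solver residual is the only non-conservative term; 1e-8 in force-accuracy
checks), neighbor-list skin 2 Å by default and smaller in boxes whose
half-edge the cutoff nearly exhausts.

## Known limitations

* Permanent multipoles stop at lab-frame dipoles; no quadrupoles, no
  rotating local multipole frames, hence no multipole torques.
* Direct Ewald (O(N^1.5–2)) instead of mesh Ewald; fine at desk scale,
  wrong tool beyond ~10³ atoms.
* Default mutual induction is real-space-restricted (see above).
* Berendsen pressure control is weak-coupling, not a true NPT ensemble.
* No constraints (SHAKE/RATTLE), no triclinic cells, no electrostatic
  embedding of the ML region (the partition is mechanical/subtractive),
  single ML region only, no training of networks.
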