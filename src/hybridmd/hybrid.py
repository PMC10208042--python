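"""Hybrid ML-solute / polarizable-solvent potential.

The hybrid energy is a mechanical (subtractive) embedding

    V_HYB(P u W) = V_FF(P u W) + V_ML(P) - V_FF(P)

where P is the solute and W the environment: the force field describes the
solvent-solvent and solvent-solute interactions, while the solute-internal
surface comes from the ML model, which only ever sees solute atoms.  The
subtracted V_FF(P) is evaluated on the isolated (non-periodic) solute with
unscaled parameters, so it — like V_ML(P) — is independent of the
alchemical lambdas.

The difference potential dV_ML = V_ML(P) - V_FF(P) collects the slowly
varying part of the hybrid force and is what the multi-timestep integrators
evaluate at the outermost level.  A divergence monitor watches |dV_ML| for
drift: a chemical reaction on the reactive ML surface has no counterpart on
the force field and desynchronizes the two potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .forcefield import ForceField
from .system import AtomicSystem, EnergyReport, Partition


@dataclass
class HybridPotential:
    """Force-field handle, ML handle and the solute/environment partition."""

    ff: ForceField
    ml: object                      # MLPModel, MLPEnsemble or FF-mimic
    partition: Partition
    #: warm-start the induced-dipole solve from the previous configuration;
    #: disable for bit-reproducible single-point comparisons
    warm_start: bool = True
    _ff_solute: ForceField = field(default=None, repr=False)

    def __post_init__(self):
        if self.partition.n_solute == 0:
            raise ValueError("hybrid potential needs a non-empty solute")
        if self._ff_solute is None:
            # separate evaluator: the isolated-solute term keeps its own
            # induced-dipole warm start and needs no neighbor list
            self._ff_solute = ForceField(self.ff.settings)

    def solute_mask(self, n_atoms: int) -> np.ndarray:
        mask = np.zeros(n_atoms, dtype=bool)
        mask[self.partition.solute_indices] = True
        return mask

    def _solute_system(self, system: AtomicSystem) -> AtomicSystem:
        sol = self.partition.solute_indices
        return AtomicSystem(
            species=[system.species[i] for i in sol],
            coordinates=system.coordinates[sol],
            box=system.box,
            parameters=system.parameters.subset(sol),
        )

    def ml_energy_forces(self, system: AtomicSystem) -> EnergyReport:
        """V_ML(P): the ML model applied to the solute atoms only."""
        sol = self.partition.solute_indices
        species = [system.species[i] for i in sol]
        for s in set(species):
            if hasattr(self.ml, "elements") and s not in self.ml.elements:
                raise ValueError(
                    f"solute element {s!r} is not supported by the ML model")
        rep = self.ml.energy_forces(species, system.coordinates[sol])
        forces = np.zeros((system.n_atoms, 3))
        forces[sol] = rep.forces
        return EnergyReport(components={"ml": rep.total}, forces=forces)

    def ff_solute_energy_forces(self, system: AtomicSystem) -> EnergyReport:
        """V_FF(P): isolated-solute force-field evaluation (non-periodic)."""
        sol = self.partition.solute_indices
        sub = self._solute_system(system)
        rep = self._ff_solute.energy_forces(sub, periodic=False,
                                            pol_tolerance=self.ff.settings.pol_tolerance)
        forces = np.zeros((system.n_atoms, 3))
        forces[sol] = rep.forces
        return EnergyReport(components={"ff_solute": rep.total}, forces=forces)

    def energy_forces(self, system: AtomicSystem, lam_ele: float = 1.0,
                      lam_vdw: float = 1.0) -> EnergyReport:
        """V_HYB = V_FF(P u W; lambda) + V_ML(P) - V_FF(P)."""
        if self.partition.environment_indices.size == 0:
            # pure-ML limit: V_FF(PuW) and V_FF(P) cancel identically
            return self.ml_energy_forces(system)
        mask = self.solute_mask(system.n_atoms)
        full = self.ff.energy_forces(system, lam_ele=lam_ele, lam_vdw=lam_vdw,
                                     solute_mask=mask,
                                     reuse_mu=self.warm_start)
        ml = self.ml_energy_forces(system)
        ffp = self.ff_solute_energy_forces(system)
        report = EnergyReport.zero(system.n_atoms)
        report.add(full, prefix="ff_")
        report.components["ml"] = ml.total
        report.components["ff_solute_subtracted"] = -ffp.total
        report.forces = report.forces + ml.forces - ffp.forces
        return report

    def delta_ml_energy_forces(self, system: AtomicSystem) -> EnergyReport:
        """dV_ML(P) = V_ML(P) - V_FF(P); forces live on solute atoms only."""
        ml = self.ml_energy_forces(system)
        ffp = self.ff_solute_energy_forces(system)
        return EnergyReport(
            components={"delta_ml": ml.total - ffp.total},
            forces=ml.forces - ffp.forces,
        )


class MonitorStatus(str, Enum):
    OK = "ok"
    WARN = "warn"
    HALT = "halt-recommended"


def monitor_divergence(delta_ml_samples, window: int = 50,
                       threshold: float = 5.0) -> MonitorStatus:
    """Flag drift of the ML/FF difference potential along a trajectory.

    Compares the running mean of |dV_ML| over the trailing ``window``
    samples against the mean over the initial window.  A drift beyond
    ``threshold`` (kcal/mol) suggests the two surfaces desynchronized
    (e.g. an intramolecular reaction on the reactive ML surface) and the
    simulation should stop; half the threshold earns a warning.
    """
    x = np.abs(np.asarray(list(delta_ml_samples), dtype=float))
    if x.size < 2:
        raise ValueError("need at least two samples to monitor divergence")
    w = min(window, x.size)
    ref = float(x[:w].mean())
    drift = float(np.abs(x[-w:].mean() - ref))
    if drift > threshold:
        return MonitorStatus.HALT
    if drift > threshold / 2.0:
        return MonitorStatus.WARN
    return MonitorStatus.OK
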