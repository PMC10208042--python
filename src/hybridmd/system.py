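"""Periodic atomic systems, force-field parameters and partitions.

The containers here are deliberately plain: numpy arrays wrapped in light
dataclasses, shared by the neighbor search, the force field, the descriptor
machinery and the integrators.  Orthorhombic boxes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASSES, KB, SUPPORTED_ELEMENTS


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic cell described by its three edge lengths (A)."""

    edge_lengths: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edge_lengths, dtype=float).reshape(3)
        if not np.all(edges > 0):
            raise ValueError("box edges must be positive")
        object.__setattr__(self, "edge_lengths", edges)

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    @property
    def min_edge(self) -> float:
        return float(np.min(self.edge_lengths))

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates into [0, L) per axis."""
        return np.mod(coords, self.edge_lengths)


def minimum_image(displacement: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Minimum-image convention displacement, each component in [-L/2, L/2).

    Idempotent; the lower edge of the half-open interval is kept so that a
    displacement of exactly +L/2 maps to -L/2.
    """
    disp = np.asarray(displacement, dtype=float)
    edges = box.edge_lengths
    return disp - edges * np.floor(disp / edges + 0.5)


@dataclass
class BondTerm:
    """Anharmonic bond stretch: E = k dr^2 (1 + c3 dr + c4 dr^2)."""

    i: int
    j: int
    r0: float          # A
    k: float           # kcal/mol/A^2
    cubic: float = 0.0     # A^-1
    quartic: float = 0.0   # A^-2


@dataclass
class AngleTerm:
    """Anharmonic angle bend about atom j: E = k dth^2 (1 + c3 dth + c4 dth^2),
    dth in radians."""

    i: int
    j: int
    k_atom: int
    theta0: float      # radians
    k: float           # kcal/mol/rad^2
    cubic: float = 0.0
    quartic: float = 0.0


@dataclass
class UreyBradleyTerm:
    """Harmonic 1-3 distance term: E = k (d - d0)^2."""

    i: int
    k_atom: int
    d0: float
    k: float


@dataclass
class FFParameters:
    """Per-atom and bonded parameters of the reduced polarizable force field.

    Electrostatics is truncated at point charges plus permanent point
    dipoles; isotropic polarizabilities drive the induced-dipole model with
    Thole exponential damping (dimensionless parameter ``thole_a``).
    """

    charges: np.ndarray                 # (n,), e
    dipoles: np.ndarray                 # (n, 3), e*A, lab frame
    polarizabilities: np.ndarray        # (n,), A^3
    vdw_r0: np.ndarray                  # (n,), A
    vdw_eps: np.ndarray                 # (n,), kcal/mol
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    urey_bradley: list[UreyBradleyTerm] = field(default_factory=list)
    thole_a: float = 0.39

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        n = self.charges.shape[0]
        self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(n, 3)
        self.polarizabilities = np.asarray(self.polarizabilities, dtype=float)
        self.vdw_r0 = np.asarray(self.vdw_r0, dtype=float)
        self.vdw_eps = np.asarray(self.vdw_eps, dtype=float)
        if np.any(self.polarizabilities < 0):
            raise ValueError("polarizabilities must be >= 0")
        if np.any(self.vdw_eps < 0):
            raise ValueError("vdW epsilon must be >= 0")
        if np.any(self.vdw_r0 <= 0):
            raise ValueError("vdW r0 must be > 0")

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]

    def bonded_pairs(self) -> set[tuple[int, int]]:
        """Unordered 1-2 pairs."""
        return {tuple(sorted((b.i, b.j))) for b in self.bonds}

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Unordered 1-2 and 1-3 pairs excluded from non-bonded terms."""
        excl = self.bonded_pairs()
        for a in self.angles:
            excl.add(tuple(sorted((a.i, a.k_atom))))
        for u in self.urey_bradley:
            excl.add(tuple(sorted((u.i, u.k_atom))))
        # 1-3 pairs implied by the bond graph even without an angle term
        neigh: dict[int, set[int]] = {}
        for b in self.bonds:
            neigh.setdefault(b.i, set()).add(b.j)
            neigh.setdefault(b.j, set()).add(b.i)
        for center, nb in neigh.items():
            for a in nb:
                for b in nb:
                    if a < b:
                        excl.add((a, b))
        return excl

    def subset(self, indices: np.ndarray) -> "FFParameters":
        """Parameters restricted to ``indices``; bonded terms re-indexed.

        Raises if a bonded term straddles the boundary.
        """
        indices = np.asarray(indices, dtype=int)
        remap = {int(old): new for new, old in enumerate(indices)}
        inside = set(remap)

        def _map_term(atoms):
            if any(a not in inside for a in atoms):
                raise ValueError(
                    "bonded term crosses the region boundary: atoms %s" % (atoms,)
                )
            return [remap[a] for a in atoms]

        bonds, angles, ubs = [], [], []
        for b in self.bonds:
            if b.i in inside or b.j in inside:
                i, j = _map_term((b.i, b.j))
                bonds.append(replace(b, i=i, j=j))
        for a in self.angles:
            if a.i in inside or a.j in inside or a.k_atom in inside:
                i, j, k = _map_term((a.i, a.j, a.k_atom))
                angles.append(replace(a, i=i, j=j, k_atom=k))
        for u in self.urey_bradley:
            if u.i in inside or u.k_atom in inside:
                i, k = _map_term((u.i, u.k_atom))
                ubs.append(replace(u, i=i, k_atom=k))
        return FFParameters(
            charges=self.charges[indices],
            dipoles=self.dipoles[indices],
            polarizabilities=self.polarizabilities[indices],
            vdw_r0=self.vdw_r0[indices],
            vdw_eps=self.vdw_eps[indices],
            bonds=bonds,
            angles=angles,
            urey_bradley=ubs,
            thole_a=self.thole_a,
        )


@dataclass
class AtomicSystem:
    """Atoms, coordinates, velocities, box and force-field parameters."""

    species: list[str]
    coordinates: np.ndarray             # (n, 3), A
    box: PeriodicBox
    parameters: FFParameters | None = None
    velocities: np.ndarray | None = None   # (n, 3), A/fs
    masses: np.ndarray | None = None       # (n,), amu

    def __post_init__(self):
        self.species = list(self.species)
        for s in self.species:
            if s not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {s!r}")
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = self.coordinates.shape[0]
        if len(self.species) != n:
            raise ValueError("species/coordinates length mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.array([ATOMIC_MASSES[s] for s in self.species])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if np.any(self.masses <= 0):
                raise ValueError("masses must be positive")
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        else:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            species=list(self.species),
            coordinates=self.coordinates.copy(),
            box=self.box,
            parameters=self.parameters,
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
        )


@dataclass(frozen=True)
class Partition:
    """Solute (P) / environment (W) split of the atom indices."""

    solute_indices: np.ndarray
    environment_indices: np.ndarray

    @property
    def n_solute(self) -> int:
        return self.solute_indices.shape[0]


@dataclass
class EnergyReport:
    """Component-resolved potential energy (kcal/mol) and forces
    (kcal/mol/A).  The total is always the sum of the components."""

    components: dict[str, float]
    forces: np.ndarray

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    @staticmethod
    def zero(n_atoms: int) -> "EnergyReport":
        return EnergyReport(components={}, forces=np.zeros((n_atoms, 3)))

    def add(self, other: "EnergyReport", prefix: str = "") -> "EnergyReport":
        for name, val in other.components.items():
            key = prefix + name
            self.components[key] = self.components.get(key, 0.0) + val
        self.forces = self.forces + other.forces
        return self


def apply_hmr(system: AtomicSystem, factor: float) -> AtomicSystem:
    """Hydrogen mass repartitioning.

    Multiplies each hydrogen mass by ``factor`` and subtracts the added mass
    from the unique heavy atom it is bonded to, so the total mass is
    conserved exactly.  Longer outer timesteps become stable because the
    fastest H-stretch frequencies drop.
    """
    if factor < 1:
        raise ValueError("HMR factor must be >= 1")
    if system.parameters is None:
        raise ValueError("HMR needs bonded topology in system.parameters")
    new = system.copy()
    masses = new.masses
    for idx, sp in enumerate(system.species):
        if sp != "H":
            continue
        partners = [
            b.j if b.i == idx else b.i
            for b in system.parameters.bonds
            if idx in (b.i, b.j)
        ]
        heavy = [p for p in partners if system.species[p] != "H"]
        if len(heavy) != 1:
            raise ValueError(
                f"H atom {idx} must be bonded to exactly one heavy atom "
                f"(found {len(heavy)})"
            )
        delta = (factor - 1.0) * system.masses[idx]
        if masses[heavy[0]] - delta <= 0:
            raise ValueError(
                f"HMR factor {factor} would drive atom {heavy[0]} "
                f"to non-positive mass"
            )
        masses[idx] += delta
        masses[heavy[0]] -= delta
    return new


def partition_system(system: AtomicSystem, solute_selection) -> Partition:
    """Build a solute/environment partition from an index set.

    The hybrid scheme covalently isolates the solute, so any bonded term
    crossing the boundary is rejected.
    """
    sol = np.unique(np.asarray(list(solute_selection), dtype=int))
    if sol.size == 0:
        raise ValueError("solute selection is empty; hybrid runs need P != {}")
    if sol.min() < 0 or sol.max() >= system.n_atoms:
        raise ValueError("solute indices out of range")
    if len(sol) != len(list(solute_selection)):
        raise ValueError("solute indices must be unique")
    inside = set(int(i) for i in sol)
    if system.parameters is not None:
        for b in system.parameters.bonds:
            if (b.i in inside) != (b.j in inside):
                raise ValueError(
                    f"bond ({b.i},{b.j}) crosses the solute/environment boundary"
                )
        for a in system.parameters.angles:
            flags = [a.i in inside, a.j in inside, a.k_atom in inside]
            if any(flags) and not all(flags):
                raise ValueError(
                    f"angle ({a.i},{a.j},{a.k_atom}) crosses the boundary"
                )
    env = np.setdiff1d(np.arange(system.n_atoms), sol)
    return Partition(solute_indices=sol, environment_indices=env)


def instantaneous_temperature(system: AtomicSystem, n_constraints: int = 3) -> float:
    """Kinetic temperature, T = 2 KE / (N_dof kB) with N_dof = 3N - constraints.

    The default removes three degrees of freedom for the center-of-mass
    motion taken out at initialization.
    """
    from .constants import kinetic_energy

    n_dof = 3 * system.n_atoms - n_constraints
    if n_dof <= 0:
        raise ValueError("no internal degrees of freedom")
    ke = kinetic_energy(system.masses, system.velocities)
    return 2.0 * ke / (n_dof * KB)


def draw_maxwell_boltzmann(
    system: AtomicSystem, temperature: float, rng: np.random.Generator,
    remove_com: bool = True,
) -> None:
    """Draw velocities from the Maxwell-Boltzmann distribution in place."""
    from .constants import INTERNAL_PER_KCAL

    sigma = np.sqrt(KB * temperature * INTERNAL_PER_KCAL / system.masses)
    system.velocities = rng.standard_normal((system.n_atoms, 3)) * sigma[:, None]
    if remove_com:
        p = (system.masses[:, None] * system.velocities).sum(axis=0)
        system.velocities -= p / system.masses.sum()
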