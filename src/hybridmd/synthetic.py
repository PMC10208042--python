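"""Seeded generators for synthetic systems and models.

Everything here is deterministic under its seed, so tests and examples can
build water boxes, toy solutes and random ML models from scratch instead of
shipping data files.

The toy water is a 3-site flexible model: AMOEBA-like charges, isotropic
polarizabilities on every site with Thole damping, an anharmonic O-H
stretch, a harmonic bend plus a Urey-Bradley 1-3 term, and buffered 14-7
van der Waals centered on both O and H.  Permanent point dipoles are kept
at zero: the package stores dipoles in the lab frame, and a fixed lab-frame
dipole cannot exert the torque a body-fixed multipole would, so molecular
permanent dipoles are left to the (orientation-free) charges while the
dipole machinery is exercised by the induced dipoles.
"""

from __future__ import annotations

import numpy as np

from .descriptors import AEVSpec
from .forcefield import FFSettings, ForceField
from .mlp import MLPEnsemble, MLPModel, SpeciesNetwork
from .system import (AngleTerm, AtomicSystem, BondTerm, EnergyReport,
                     FFParameters, PeriodicBox, UreyBradleyTerm)

# toy water geometry and parameters
_WATER_OH = 0.9572          # A
_WATER_ANGLE = np.deg2rad(104.52)
_WATER_HH = 2.0 * _WATER_OH * np.sin(_WATER_ANGLE / 2.0)

_WATER = {
    "q_O": -0.51966, "q_H": 0.25983,
    "alpha_O": 0.837, "alpha_H": 0.496,
    "k_bond": 450.0, "bond_cubic": -2.55, "bond_quartic": 3.793125,
    "k_angle": 55.0,
    "k_ub": 5.0,
    "vdw_O": (3.579, 0.11), "vdw_H": (2.70, 0.0135),
}

#: molecules per A^3 of liquid water at ambient conditions
WATER_NUMBER_DENSITY = 996.0 / 31.0**3


def _water_geometry() -> np.ndarray:
    """One water in its local frame, O at the origin."""
    half = _WATER_ANGLE / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [_WATER_OH * np.sin(half), 0.0, _WATER_OH * np.cos(half)],
        [-_WATER_OH * np.sin(half), 0.0, _WATER_OH * np.cos(half)],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def water_parameters(n_waters: int, offset: int = 0) -> FFParameters:
    """Force-field parameters for ``n_waters`` consecutive O,H,H triples."""
    n = 3 * n_waters
    charges = np.tile([_WATER["q_O"], _WATER["q_H"], _WATER["q_H"]], n_waters)
    alphas = np.tile([_WATER["alpha_O"], _WATER["alpha_H"], _WATER["alpha_H"]],
                     n_waters)
    vdw_r0 = np.tile([_WATER["vdw_O"][0], _WATER["vdw_H"][0],
                      _WATER["vdw_H"][0]], n_waters)
    vdw_eps = np.tile([_WATER["vdw_O"][1], _WATER["vdw_H"][1],
                       _WATER["vdw_H"][1]], n_waters)
    bonds, angles, ubs = [], [], []
    for w in range(n_waters):
        o, h1, h2 = offset + 3 * w, offset + 3 * w + 1, offset + 3 * w + 2
        for h in (h1, h2):
            bonds.append(BondTerm(o, h, _WATER_OH, _WATER["k_bond"],
                                  _WATER["bond_cubic"], _WATER["bond_quartic"]))
        angles.append(AngleTerm(h1, o, h2, _WATER_ANGLE, _WATER["k_angle"]))
        ubs.append(UreyBradleyTerm(h1, h2, _WATER_HH, _WATER["k_ub"]))
    return FFParameters(charges=charges, dipoles=np.zeros((n, 3)),
                        polarizabilities=alphas, vdw_r0=vdw_r0,
                        vdw_eps=vdw_eps, bonds=bonds, angles=angles,
                        urey_bradley=ubs)


def generate_water_box(n_waters: int, edge: float | None = None,
                       seed: int = 0, jitter: float = 0.15) -> AtomicSystem:
    """Jittered-lattice water box with random molecular orientations.

    When ``edge`` is omitted the box is sized to ambient liquid density.
    Oxygen sites sit on a cubic lattice with uniform jitter; the guard
    against O-O clashes (< 2.4 A) rejects infeasible densities.
    """
    if n_waters < 1:
        raise ValueError("need at least one water")
    rng = np.random.default_rng(seed)
    if edge is None:
        edge = (n_waters / WATER_NUMBER_DENSITY) ** (1.0 / 3.0)
    # jittered base lattice with guaranteed spacing; leftover waters are
    # inserted by rejection sampling against the already-placed oxygens
    lattice_oo = 2.4 + 2.0 * jitter * np.sqrt(3.0)
    m = max(int(np.floor(edge / (lattice_oo + 0.05))), 1)
    base = np.array([(i, j, k) for i in range(m) for j in range(m)
                     for k in range(m)], dtype=float)
    base = (base + 0.5) * (edge / m)
    rng.shuffle(base)
    n_base = min(n_waters, len(base))
    placed = list(base[:n_base] + rng.uniform(-jitter, jitter, size=(n_base, 3)))
    box_edges = np.array([edge] * 3)
    attempts = 0
    while len(placed) < n_waters:
        trial = rng.uniform(0.0, edge, size=3)
        d = np.abs(np.array(placed) - trial)
        d = np.minimum(d, box_edges - d)
        if np.sqrt((d**2).sum(axis=1)).min() >= 2.45:
            placed.append(trial)
        attempts += 1
        if attempts > 20000 * n_waters:
            raise ValueError(
                f"density infeasible: cannot place {n_waters} waters with "
                f"O-O distances >= 2.4 A in a {edge:.1f} A box"
            )
    sites = np.array(placed)
    local = _water_geometry()
    coords = np.empty((3 * n_waters, 3))
    for w in range(n_waters):
        rot = _random_rotation(rng)
        coords[3 * w:3 * w + 3] = sites[w] + local @ rot.T
    species = ["O", "H", "H"] * n_waters
    return AtomicSystem(species=species, coordinates=coords,
                        box=PeriodicBox([edge] * 3),
                        parameters=water_parameters(n_waters))


# ---------------------------------------------------------------------------
# toy solutes


def generate_toy_solute(kind: str, seed: int = 0) -> AtomicSystem:
    """Small bonded solutes with parameters: diatomic, ring6 (benzene-like
    C6H6) or chain (heavy-atom zig-zag)."""
    rng = np.random.default_rng(seed)
    big_box = PeriodicBox([100.0, 100.0, 100.0])
    if kind == "diatomic":
        coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        params = FFParameters(
            charges=[0.2, -0.2], dipoles=np.zeros((2, 3)),
            polarizabilities=[1.0, 1.0],
            vdw_r0=[3.8, 3.8], vdw_eps=[0.1, 0.1],
            bonds=[BondTerm(0, 1, 1.5, 300.0)],
        )
        return AtomicSystem(species=["C", "C"], coordinates=coords,
                            box=big_box, parameters=params)
    if kind == "ring6":
        r_cc = 1.39
        r_ch = 1.09
        ang = np.arange(6) * np.pi / 3.0
        c_pos = r_cc * np.column_stack([np.cos(ang), np.sin(ang),
                                        np.zeros(6)])
        h_pos = (r_cc + r_ch) * np.column_stack([np.cos(ang), np.sin(ang),
                                                 np.zeros(6)])
        coords = np.vstack([c_pos, h_pos])
        bonds = []
        for i in range(6):
            bonds.append(BondTerm(i, (i + 1) % 6, r_cc, 350.0, -2.55, 3.79))
            bonds.append(BondTerm(i, 6 + i, r_ch, 370.0, -2.55, 3.79))
        angles = []
        for i in range(6):
            angles.append(AngleTerm((i - 1) % 6, i, (i + 1) % 6,
                                    np.deg2rad(120.0), 63.0))
            angles.append(AngleTerm((i - 1) % 6, i, 6 + i,
                                    np.deg2rad(120.0), 35.0))
            angles.append(AngleTerm((i + 1) % 6, i, 6 + i,
                                    np.deg2rad(120.0), 35.0))
        params = FFParameters(
            charges=[-0.115] * 6 + [0.115] * 6,
            dipoles=np.zeros((12, 3)),
            polarizabilities=[1.75] * 6 + [0.696] * 6,
            vdw_r0=[3.8] * 6 + [2.98] * 6,
            vdw_eps=[0.089] * 6 + [0.026] * 6,
            bonds=bonds, angles=angles,
        )
        return AtomicSystem(species=["C"] * 6 + ["H"] * 6, coordinates=coords,
                            box=big_box, parameters=params)
    if kind.startswith("chain"):
        n = int(kind[5:].strip("()") or 4) if len(kind) > 5 else 4
        # zig-zag carbon chain: n-1 bonds, n-2 angles
        r0 = 1.53
        theta0 = np.deg2rad(112.0)
        coords = np.zeros((n, 3))
        step = r0 * np.sin(theta0 / 2.0), r0 * np.cos(theta0 / 2.0)
        for i in range(1, n):
            coords[i] = coords[i - 1] + [step[0], step[1] * (-1) ** i, 0.0]
        bonds = [BondTerm(i, i + 1, r0, 300.0, -2.55, 3.79)
                 for i in range(n - 1)]
        angles = [AngleTerm(i, i + 1, i + 2, theta0, 58.0)
                  for i in range(n - 2)]
        q = rng.uniform(-0.1, 0.1, size=n)
        q -= q.mean()
        params = FFParameters(
            charges=q, dipoles=np.zeros((n, 3)),
            polarizabilities=np.full(n, 1.3),
            vdw_r0=np.full(n, 3.8), vdw_eps=np.full(n, 0.1),
            bonds=bonds, angles=angles,
        )
        return AtomicSystem(species=["C"] * n, coordinates=coords,
                            box=big_box, parameters=params)
    raise ValueError(f"unknown solute kind {kind!r}")


def merge_parameters(a: FFParameters, b: FFParameters) -> FFParameters:
    """Concatenate two parameter sets; ``b``'s atom indices are shifted."""
    from dataclasses import replace
    off = a.n_atoms
    return FFParameters(
        charges=np.concatenate([a.charges, b.charges]),
        dipoles=np.vstack([a.dipoles, b.dipoles]),
        polarizabilities=np.concatenate([a.polarizabilities,
                                         b.polarizabilities]),
        vdw_r0=np.concatenate([a.vdw_r0, b.vdw_r0]),
        vdw_eps=np.concatenate([a.vdw_eps, b.vdw_eps]),
        bonds=a.bonds + [replace(t, i=t.i + off, j=t.j + off) for t in b.bonds],
        angles=a.angles + [replace(t, i=t.i + off, j=t.j + off,
                                   k_atom=t.k_atom + off) for t in b.angles],
        urey_bradley=a.urey_bradley + [replace(t, i=t.i + off,
                                               k_atom=t.k_atom + off)
                                       for t in b.urey_bradley],
        thole_a=a.thole_a,
    )


def solvate(solute: AtomicSystem, n_waters: int, seed: int = 0,
            clash_distance: float = 2.55) -> AtomicSystem:
    """Center the solute in a water box, dropping waters that clash.

    The solute occupies the first atom indices, so the hybrid partition is
    simply range(n_solute).
    """
    request = n_waters + max(4, solute.n_atoms)
    keep = []
    for _ in range(6):
        box_sys = generate_water_box(request, seed=seed)
        box = box_sys.box
        center = box.edge_lengths / 2.0
        sol_coords = solute.coordinates - solute.coordinates.mean(axis=0) + center
        keep = []
        n_w = len(box_sys.species) // 3
        for w in range(n_w):
            ow = box_sys.coordinates[3 * w]
            d = np.linalg.norm(sol_coords - ow, axis=1).min()
            if d > clash_distance:
                keep.append(w)
            if len(keep) == n_waters:
                break
        if len(keep) == n_waters:
            break
        request = int(np.ceil(request * 1.3)) + 2
    if len(keep) < n_waters:
        raise ValueError("could not place the requested number of waters")
    wat_coords = np.vstack([box_sys.coordinates[3 * w:3 * w + 3]
                            for w in keep])
    params = merge_parameters(solute.parameters, water_parameters(len(keep)))
    return AtomicSystem(
        species=list(solute.species) + ["O", "H", "H"] * len(keep),
        coordinates=np.vstack([sol_coords, wat_coords]),
        box=box,
        parameters=params,
    )


# ---------------------------------------------------------------------------
# synthetic ML models


def generate_random_mlp(elements=("H", "C", "O"), layer_sizes=(32, 16),
                        seed: int = 0, scale: float = 0.1,
                        aev_spec: AEVSpec | None = None,
                        energy_bound: float = 10.0) -> MLPModel:
    """Random feed-forward model over AEV inputs, output-calibrated so that
    per-atom energies stay below ``energy_bound`` kcal/mol on probe AEVs
    (keeps toy MD stable)."""
    rng = np.random.default_rng(seed)
    spec = aev_spec or AEVSpec(elements=tuple(elements))
    dim = spec.aev_length
    networks = {}
    for el in spec.elements:
        sizes = [dim, *layer_sizes, 1]
        ws = [rng.normal(scale=scale / np.sqrt(sizes[l]),
                         size=(sizes[l + 1], sizes[l]))
              for l in range(len(sizes) - 1)]
        bs = [rng.normal(scale=0.01 * scale, size=(sizes[l + 1],))
              for l in range(len(sizes) - 1)]
        networks[el] = SpeciesNetwork(ws, bs)
    model = MLPModel(aev_spec=spec, networks=networks,
                     shifts={el: 0.0 for el in spec.elements},
                     metadata={"seed": int(seed), "note": "random synthetic model"})
    if scale > 0:
        probe = rng.uniform(0.0, 2.0, size=(16, dim))
        worst = max(abs(net.forward(g)) for net in networks.values()
                    for g in probe)
        if worst > energy_bound:
            shrink = energy_bound / worst
            for net in networks.values():
                net.weights[-1] = net.weights[-1] * shrink
                net.biases[-1] = net.biases[-1] * shrink
    return model


def generate_random_ensemble(elements=("H", "C", "O"), n_members: int = 8,
                             seed: int = 0, **kw) -> MLPEnsemble:
    """Ensemble of independently seeded random models sharing one spec."""
    spec = kw.pop("aev_spec", None) or AEVSpec(elements=tuple(elements))
    members = [generate_random_mlp(elements, seed=seed + 1000 * k,
                                   aev_spec=spec, **kw)
               for k in range(n_members)]
    return MLPEnsemble(members)


class CompositeML:
    """Sum of ML-interface models evaluated on the same solute."""

    def __init__(self, *members):
        if not members:
            raise ValueError("need at least one member")
        self.members = members
        self.elements = members[0].elements

    def energy_forces(self, species, coords) -> EnergyReport:
        reps = [m.energy_forces(species, coords) for m in self.members]
        total = sum(r.total for r in reps)
        forces = sum(r.forces for r in reps)
        return EnergyReport(components={"ml": total}, forces=forces)


def ff_mimic_with_noise(params: FFParameters, elements, seed: int = 0,
                        scale: float = 0.05,
                        settings: "FFSettings | None" = None) -> CompositeML:
    """FF-mimic plus a small random network correction.

    A stable stand-in for a trained solute model: it keeps the bonded
    skeleton of the force field (so hybrid MD does not dissociate the
    solute) while making dV_ML = V_ML - V_FF(P) small but non-zero, which
    is exactly the regime the multi-timestep splitting and the reweighting
    fallback assume.
    """
    mimic = FFMimicML(params, settings)
    noise = generate_random_mlp(tuple(elements), seed=seed, scale=scale)
    return CompositeML(mimic, noise)


class FFMimicML:
    """ML-interface adapter that evaluates the isolated-solute force field.

    Plugged into the hybrid potential it realizes the exact cancellation
    V_FF(PuW) + V_mimic(P) - V_FF(P) = V_FF(PuW), which is the algebraic
    identity every hybrid test leans on.  Also useful to generate pure-FF
    trajectories through the hybrid machinery for reweighting.
    """

    def __init__(self, params: FFParameters, settings: FFSettings | None = None):
        self.params = params
        self.settings = settings or FFSettings()
        self._ff = ForceField(self.settings)
        self.elements = ("H", "C", "N", "O", "S", "F", "Cl")

    def energy_forces(self, species, coords) -> EnergyReport:
        sub = AtomicSystem(species=list(species),
                           coordinates=np.asarray(coords, dtype=float),
                           box=PeriodicBox([1e6] * 3), parameters=self.params)
        rep = self._ff.energy_forces(sub, periodic=False,
                                     pol_tolerance=self.settings.pol_tolerance)
        return EnergyReport(components={"ml": rep.total}, forces=rep.forces)
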