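"""File formats: extended XYZ, minimal PDB (read-only), YAML parameters,
HDF5 work samples and trajectories, JSON results.

Extended XYZ is the primary geometry format (self-describing element
symbols plus a Lattice record in the comment line).  PDB reading is
delegated to MDAnalysis and supports the ATOM/HETATM + CRYST1 subset
needed to seed a simulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .system import (AngleTerm, AtomicSystem, BondTerm, FFParameters,
                     PeriodicBox, UreyBradleyTerm)

# ---------------------------------------------------------------------------
# extended XYZ


def write_xyz(system: AtomicSystem, path, comment: str = "") -> None:
    """Extended-XYZ with an orthorhombic Lattice record."""
    L = system.box.edge_lengths
    lattice = " ".join(
        f"{v:.10g}" for v in
        [L[0], 0, 0, 0, L[1], 0, 0, 0, L[2]]
    )
    lines = [str(system.n_atoms),
             f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 {comment}'.rstrip()]
    for sp, xyz in zip(system.species, system.coordinates):
        lines.append(f"{sp} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> AtomicSystem:
    """Read (extended) XYZ; falls back to a huge box if no Lattice record."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError("truncated XYZ file")
    n = int(lines[0].split()[0])
    comment = lines[1]
    box = PeriodicBox([1e6] * 3)
    if "Lattice=" in comment:
        raw = comment.split('Lattice="')[1].split('"')[0]
        cell = np.array([float(v) for v in raw.split()]).reshape(3, 3)
        if np.abs(cell - np.diag(np.diag(cell))).max() > 1e-10:
            raise ValueError("only orthorhombic lattices are supported")
        box = PeriodicBox(np.diag(cell))
    species, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        species.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    if len(species) != n:
        raise ValueError("XYZ atom count mismatch")
    return AtomicSystem(species=species, coordinates=np.array(coords), box=box)


def read_pdb(path) -> AtomicSystem:
    """Minimal PDB reader (ATOM/HETATM records, CRYST1 box) via MDAnalysis."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        species = [str(e).capitalize() for e in u.atoms.elements] \
            if hasattr(u.atoms, "elements") else \
            [str(nm)[0].upper() for nm in u.atoms.names]
        coords = u.atoms.positions.astype(float)
        if u.dimensions is not None and u.dimensions[:3].min() > 0:
            box = PeriodicBox(u.dimensions[:3].astype(float))
        else:
            box = PeriodicBox([1e6] * 3)
    return AtomicSystem(species=species, coordinates=coords, box=box)


# ---------------------------------------------------------------------------
# parameter files


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def save_parameters(params: FFParameters, path) -> None:
    d = {
        "charges": params.charges.tolist(),
        "dipoles": params.dipoles.tolist(),
        "polarizabilities": params.polarizabilities.tolist(),
        "vdw_r0": params.vdw_r0.tolist(),
        "vdw_eps": params.vdw_eps.tolist(),
        "thole_a": float(params.thole_a),
        "bonds": [asdict(b) for b in params.bonds],
        "angles": [asdict(a) for a in params.angles],
        "urey_bradley": [asdict(u) for u in params.urey_bradley],
    }
    Path(path).write_text(yaml.safe_dump(_plain(d), default_flow_style=None))


def load_parameters(path) -> FFParameters:
    d = yaml.safe_load(Path(path).read_text())
    return FFParameters(
        charges=np.array(d["charges"]),
        dipoles=np.array(d["dipoles"]),
        polarizabilities=np.array(d["polarizabilities"]),
        vdw_r0=np.array(d["vdw_r0"]),
        vdw_eps=np.array(d["vdw_eps"]),
        thole_a=d.get("thole_a", 0.39),
        bonds=[BondTerm(**b) for b in d.get("bonds", [])],
        angles=[AngleTerm(**a) for a in d.get("angles", [])],
        urey_bradley=[UreyBradleyTerm(**u) for u in d.get("urey_bradley", [])],
    )


# ---------------------------------------------------------------------------
# HDF5 samples and trajectories


def save_work_samples(path, samples_list, temperature: float,
                      provenance: dict | None = None) -> None:
    """Window-pair work samples to HDF5 (one group per adjacent pair)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["temperature"] = temperature
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)
        for w, s in enumerate(samples_list):
            g = f.create_group(f"pair_{w:03d}")
            g.create_dataset("forward", data=np.asarray(s.forward))
            g.create_dataset("backward", data=np.asarray(s.backward))


def load_work_samples(path):
    from .alchemy import WorkSamples
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        t = float(f.attrs["temperature"])
        for key in sorted(k for k in f.keys() if k.startswith("pair_")):
            out.append(WorkSamples(f[key]["forward"][...],
                                   f[key]["backward"][...], t))
    return out


def save_trajectory(path, frames, species, box: PeriodicBox,
                    provenance: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=np.asarray(frames))
        f.create_dataset("box", data=box.edge_lengths)
        f.attrs["species"] = json.dumps(list(species))
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def write_result_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
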