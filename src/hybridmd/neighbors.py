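"""Linked-cell neighbor search with a brute-force fallback.

Builds the unique unordered pair list of atoms within cutoff + skin under
the minimum-image convention.  When the box accommodates at least three
cells per axis the linked-cell path is used (linear cost at fixed density);
otherwise an exact O(N^2) minimum-image sweep gives the same pair set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .system import AtomicSystem, PeriodicBox, minimum_image


@dataclass
class CellGrid:
    """Spatial binning of wrapped coordinates into cells of edge >= cutoff+skin."""

    n_cells: np.ndarray          # (3,) cells per axis
    cell_of_atom: np.ndarray     # (n,) flattened cell index
    box: PeriodicBox
    cutoff: float
    skin: float


@dataclass
class PairList:
    """Unique unordered pairs within cutoff + skin, with build-time snapshot."""

    pairs: np.ndarray            # (m, 2) int, i < j
    displacements: np.ndarray    # (m, 3) minimum-image r_i - r_j at build time
    distances: np.ndarray        # (m,)
    cutoff: float
    skin: float
    build_coordinates: np.ndarray
    box: PeriodicBox

    def within(self, cutoff: float):
        """Boolean mask selecting pairs inside a (smaller) consumer cutoff."""
        if cutoff > self.cutoff + self.skin:
            raise ValueError("consumer cutoff exceeds the list's reach")
        return self.distances < cutoff


def _check_cutoff(box: PeriodicBox, cutoff: float, skin: float) -> None:
    if cutoff + skin > box.min_edge / 2 + 1e-12:
        raise ValueError(
            f"cutoff+skin = {cutoff + skin:.3f} A exceeds half the smallest "
            f"box edge ({box.min_edge / 2:.3f} A); the minimum-image "
            f"convention would be invalid"
        )


def build_cell_list(system: AtomicSystem, cutoff: float, skin: float = 2.0) -> CellGrid:
    """Assign atoms to cells of edge >= cutoff + skin (half-open binning)."""
    _check_cutoff(system.box, cutoff, skin)
    edges = system.box.edge_lengths
    reach = cutoff + skin
    n_cells = np.maximum(np.floor(edges / reach).astype(int), 1)
    wrapped = system.box.wrap(system.coordinates)
    idx3 = np.minimum(
        np.floor(wrapped / (edges / n_cells)).astype(int), n_cells - 1
    )
    flat = (idx3[:, 0] * n_cells[1] + idx3[:, 1]) * n_cells[2] + idx3[:, 2]
    return CellGrid(n_cells=n_cells, cell_of_atom=flat, box=system.box,
                    cutoff=cutoff, skin=skin)


def brute_force_pairs(system: AtomicSystem, cutoff: float, skin: float = 0.0) -> PairList:
    """Exact O(N^2) minimum-image pair list; the oracle for the cell path."""
    _check_cutoff(system.box, cutoff, skin)
    coords = system.coordinates
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    disp = minimum_image(coords[iu] - coords[ju], system.box)
    dist = np.linalg.norm(disp, axis=1)
    keep = dist < cutoff + skin
    return PairList(
        pairs=np.column_stack((iu[keep], ju[keep])),
        displacements=disp[keep],
        distances=dist[keep],
        cutoff=cutoff,
        skin=skin,
        build_coordinates=coords.copy(),
        box=system.box,
    )


def build_pair_list(system: AtomicSystem, cutoff: float, skin: float = 2.0) -> PairList:
    """Pair list via linked cells where the grid is at least 3^3, else brute force."""
    _check_cutoff(system.box, cutoff, skin)
    grid = build_cell_list(system, cutoff, skin)
    if np.any(grid.n_cells < 3):
        # too few cells for a 27-stencil without double counting images
        return brute_force_pairs(system, cutoff, skin)

    coords = system.coordinates
    n = coords.shape[0]
    ncx, ncy, ncz = (int(v) for v in grid.n_cells)
    ncells = ncx * ncy * ncz
    order = np.argsort(grid.cell_of_atom, kind="stable")
    sorted_cells = grid.cell_of_atom[order]
    starts = np.searchsorted(sorted_cells, np.arange(ncells))
    ends = np.searchsorted(sorted_cells, np.arange(ncells), side="right")

    members = [order[starts[c]:ends[c]] for c in range(ncells)]
    pair_i, pair_j = [], []
    stencil = list(product((-1, 0, 1), repeat=3))
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                home = members[c]
                if home.size == 0:
                    continue
                for dx, dy, dz in stencil:
                    nx, ny, nz = (cx + dx) % ncx, (cy + dy) % ncy, (cz + dz) % ncz
                    c2 = (nx * ncy + ny) * ncz + nz
                    if c2 < c:
                        continue
                    other = members[c2]
                    if other.size == 0:
                        continue
                    if c2 == c:
                        ii, jj = np.triu_indices(home.size, k=1)
                        pair_i.append(home[ii])
                        pair_j.append(home[jj])
                    else:
                        ii, jj = np.meshgrid(home, other, indexing="ij")
                        pair_i.append(ii.ravel())
                        pair_j.append(jj.ravel())
    if pair_i:
        pi = np.concatenate(pair_i)
        pj = np.concatenate(pair_j)
    else:
        pi = pj = np.empty(0, dtype=int)
    lo = np.minimum(pi, pj)
    hi = np.maximum(pi, pj)
    # neighboring cells can alias under periodic wrap; deduplicate
    key = lo.astype(np.int64) * n + hi
    _, uniq = np.unique(key, return_index=True)
    lo, hi = lo[uniq], hi[uniq]
    disp = minimum_image(coords[lo] - coords[hi], system.box)
    dist = np.linalg.norm(disp, axis=1)
    keep = dist < cutoff + skin
    return PairList(
        pairs=np.column_stack((lo[keep], hi[keep])),
        displacements=disp[keep],
        distances=dist[keep],
        cutoff=cutoff,
        skin=skin,
        build_coordinates=coords.copy(),
        box=system.box,
    )


def needs_rebuild(pairlist: PairList, system: AtomicSystem) -> bool:
    """True when any atom moved >= skin/2 since the list was built."""
    disp = minimum_image(
        system.coordinates - pairlist.build_coordinates, pairlist.box
    )
    max_disp = float(np.max(np.linalg.norm(disp, axis=1))) if disp.size else 0.0
    return max_disp >= pairlist.skin / 2.0


def refresh_pair_list(pairlist: PairList, system: AtomicSystem) -> PairList:
    """Rebuild if needed, else recompute displacements on the cached pairs."""
    if needs_rebuild(pairlist, system):
        return build_pair_list(system, pairlist.cutoff, pairlist.skin)
    i, j = pairlist.pairs[:, 0], pairlist.pairs[:, 1]
    disp = minimum_image(
        system.coordinates[i] - system.coordinates[j], pairlist.box
    )
    return PairList(
        pairs=pairlist.pairs,
        displacements=disp,
        distances=np.linalg.norm(disp, axis=1),
        cutoff=pairlist.cutoff,
        skin=pairlist.skin,
        build_coordinates=pairlist.build_coordinates,
        box=pairlist.box,
    )
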