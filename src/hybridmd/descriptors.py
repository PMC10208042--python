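"""Atomic environment vectors (AEVs) and the sorted local-environment descriptor.

The AEV of an atom concatenates, per neighbor species, radial symmetry
functions (Gaussian shells damped by a cosine cutoff) and, per unordered
species pair, angular symmetry functions probing the angle subtended at the
central atom.  The layout is species-blocked and fixed by the ordered
element list serialized with every model, so an AEV is only meaningful
together with its :class:`AEVSpec`.

All functions are smooth (C^1) in the coordinates, which is what makes the
analytic Jacobian — and hence the ML forces — well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import PeriodicBox, minimum_image

_TINY = 1e-12


def _default_radial_shifts() -> np.ndarray:
    return np.linspace(0.9, 5.2, 17)[:-1]  # 16 shifts in [0.9, Rc)


def _default_angular_grid() -> dict:
    rs = np.linspace(0.9, 3.5, 5)[:-1]     # 4 shifts
    ts = (np.arange(8) + 0.5) * np.pi / 8  # 8 angle centers
    rr, tt = np.meshgrid(rs, ts, indexing="ij")
    return {
        "shifts": rr.ravel(),
        "thetas": tt.ravel(),
        "eta": np.full(32, 8.0),
        "zeta": np.full(32, 32.0),
    }


@dataclass
class AEVSpec:
    """Descriptor parameter grids and the ordered element alphabet."""

    elements: tuple[str, ...]
    radial_cutoff: float = 5.2      # A
    angular_cutoff: float = 3.5     # A
    radial_eta: np.ndarray = None       # A^-2, per radial grid entry
    radial_shifts: np.ndarray = None    # A
    angular_eta: np.ndarray = None
    angular_shifts: np.ndarray = None
    angular_thetas: np.ndarray = None   # rad
    angular_zeta: np.ndarray = None

    def __post_init__(self):
        self.elements = tuple(self.elements)
        if self.radial_shifts is None:
            self.radial_shifts = _default_radial_shifts() * (self.radial_cutoff / 5.2)
        self.radial_shifts = np.asarray(self.radial_shifts, dtype=float)
        if self.radial_eta is None:
            self.radial_eta = np.full(self.radial_shifts.shape, 16.0)
        self.radial_eta = np.asarray(self.radial_eta, dtype=float)
        if self.angular_shifts is None:
            g = _default_angular_grid()
            scale = self.angular_cutoff / 3.5
            self.angular_shifts = g["shifts"] * scale
            self.angular_thetas = g["thetas"]
            self.angular_eta = g["eta"]
            self.angular_zeta = g["zeta"]
        self.angular_shifts = np.asarray(self.angular_shifts, dtype=float)
        self.angular_thetas = np.asarray(self.angular_thetas, dtype=float)
        self.angular_eta = np.asarray(self.angular_eta, dtype=float)
        self.angular_zeta = np.asarray(self.angular_zeta, dtype=float)
        if self.radial_cutoff <= 0 or self.angular_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.radial_shifts.size == 0 or self.angular_shifts.size == 0:
            raise ValueError("parameter grids must be non-empty")

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_radial(self) -> int:
        return self.radial_shifts.size

    @property
    def n_angular(self) -> int:
        return self.angular_shifts.size

    @property
    def species_pairs(self) -> list[tuple[int, int]]:
        n = self.n_elements
        return [(a, b) for a in range(n) for b in range(a, n)]

    @property
    def aev_length(self) -> int:
        n = self.n_elements
        return n * self.n_radial + (n * (n + 1) // 2) * self.n_angular

    def radial_block(self, species_idx: int) -> slice:
        m = self.n_radial
        return slice(species_idx * m, (species_idx + 1) * m)

    def angular_block(self, pair: tuple[int, int]) -> slice:
        base = self.n_elements * self.n_radial
        k = self.species_pairs.index(tuple(sorted(pair)))
        a = self.n_angular
        return slice(base + k * a, base + (k + 1) * a)

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "radial_cutoff": float(self.radial_cutoff),
            "angular_cutoff": float(self.angular_cutoff),
            "radial_eta": self.radial_eta.tolist(),
            "radial_shifts": self.radial_shifts.tolist(),
            "angular_eta": self.angular_eta.tolist(),
            "angular_shifts": self.angular_shifts.tolist(),
            "angular_thetas": self.angular_thetas.tolist(),
            "angular_zeta": self.angular_zeta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AEVSpec":
        return cls(
            elements=tuple(d["elements"]),
            radial_cutoff=d["radial_cutoff"],
            angular_cutoff=d["angular_cutoff"],
            radial_eta=np.array(d["radial_eta"]),
            radial_shifts=np.array(d["radial_shifts"]),
            angular_eta=np.array(d["angular_eta"]),
            angular_shifts=np.array(d["angular_shifts"]),
            angular_thetas=np.array(d["angular_thetas"]),
            angular_zeta=np.array(d["angular_zeta"]),
        )


def cutoff_fn(r, r_c: float):
    """Cosine cutoff: 1/2 cos(pi r/Rc) + 1/2 inside Rc, zero beyond.

    Continuously differentiable with vanishing slope at Rc.
    """
    r = np.asarray(r, dtype=float)
    out = np.where(r < r_c, 0.5 * np.cos(np.pi * r / r_c) + 0.5, 0.0)
    return out if out.shape else float(out)


def cutoff_fn_deriv(r, r_c: float):
    r = np.asarray(r, dtype=float)
    out = np.where(r < r_c, -0.5 * np.pi / r_c * np.sin(np.pi * r / r_c), 0.0)
    return out if out.shape else float(out)


def radial_subaev(distances, eta, r_s, r_c: float) -> float:
    """Sum over neighbors of exp(-eta (R-Rs)^2) fc(R) for one grid entry."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return 0.0
    return float(np.sum(np.exp(-eta * (d - r_s) ** 2) * cutoff_fn(d, r_c)))


def angular_subaev(r_ij, r_ik, theta, eta, r_s, theta_s, zeta, r_c: float) -> float:
    """One angular symmetry-function term for a neighbor pair (j, k)."""
    fc = cutoff_fn(r_ij, r_c) * cutoff_fn(r_ik, r_c)
    ang = (1.0 + np.cos(theta - theta_s)) ** zeta
    rad = np.exp(-eta * (0.5 * (r_ij + r_ik) - r_s) ** 2)
    return float(2.0 ** (1.0 - zeta) * ang * rad * fc)


def _neighbor_displacements(coords, center, box):
    disp = coords - coords[center]
    if box is not None:
        disp = minimum_image(disp, box)
    return disp


def assemble_aev(
    coords: np.ndarray,
    species: list[str],
    center: int,
    spec: AEVSpec,
    box: PeriodicBox | None = None,
) -> np.ndarray:
    """AEV of one atom: radial blocks per species, then angular blocks per pair."""
    if species[center] not in spec.elements:
        raise ValueError(f"species {species[center]!r} not in descriptor alphabet")
    el_index = {}
    for s in set(species):
        if s not in spec.elements:
            raise ValueError(f"species {s!r} not in descriptor alphabet")
        el_index[s] = spec.elements.index(s)

    disp = _neighbor_displacements(np.asarray(coords, dtype=float), center, box)
    dist = np.linalg.norm(disp, axis=1)
    mask = (dist < spec.radial_cutoff) & (np.arange(len(species)) != center)
    nb = np.nonzero(mask)[0]
    aev = np.zeros(spec.aev_length)
    if nb.size == 0:
        return aev

    sp_idx = np.array([el_index[species[j]] for j in nb])
    d = dist[nb]
    # canonical accumulation order (species, then distance) makes the AEV
    # bitwise invariant under permutation of same-species atoms
    order = np.lexsort((d, sp_idx))
    nb, sp_idx, d = nb[order], sp_idx[order], d[order]

    # radial part: (n_nb, n_radial) terms scattered into species blocks
    terms = np.exp(-spec.radial_eta[None, :] * (d[:, None] - spec.radial_shifts[None, :]) ** 2)
    terms *= cutoff_fn(d, spec.radial_cutoff)[:, None]
    for s in np.unique(sp_idx):
        aev[spec.radial_block(int(s))] = terms[sp_idx == s].sum(axis=0)

    # angular part over unordered neighbor pairs within the angular cutoff,
    # enumerated in the canonical order fixed above
    amask = d < spec.angular_cutoff
    anb = nb[amask]
    if anb.size >= 2:
        u = disp[anb]
        du = d[amask]
        sa = sp_idx[amask]
        jj, kk = np.triu_indices(anb.size, k=1)
        rj, rk = du[jj], du[kk]
        cosang = np.einsum("ij,ij->i", u[jj], u[kk]) / (rj * rk)
        cosang = np.clip(cosang, -1.0 + _TINY, 1.0 - _TINY)
        theta = np.arccos(cosang)
        fc = (cutoff_fn(rj, spec.angular_cutoff)
              * cutoff_fn(rk, spec.angular_cutoff))
        # (n_pairs, n_angular)
        ang = (1.0 + np.cos(theta[:, None] - spec.angular_thetas[None, :])) ** spec.angular_zeta[None, :]
        rad = np.exp(-spec.angular_eta[None, :]
                     * (0.5 * (rj + rk)[:, None] - spec.angular_shifts[None, :]) ** 2)
        pref = 2.0 ** (1.0 - spec.angular_zeta)[None, :]
        terms = pref * ang * rad * fc[:, None]
        pair_sp = np.stack([np.minimum(sa[jj], sa[kk]), np.maximum(sa[jj], sa[kk])], axis=1)
        for a, b in set(map(tuple, pair_sp)):
            sel = (pair_sp[:, 0] == a) & (pair_sp[:, 1] == b)
            aev[spec.angular_block((a, b))] += terms[sel].sum(axis=0)
    return aev


def aev_jacobian(
    coords: np.ndarray,
    species: list[str],
    center: int,
    spec: AEVSpec,
    box: PeriodicBox | None = None,
) -> np.ndarray:
    """d(AEV)/d(coordinates), shape (aev_length, n_atoms, 3).

    Analytic derivatives of the radial and angular symmetry functions; the
    reference for correctness is central finite differences.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    el_index = {s: spec.elements.index(s) for s in set(species)}
    jac = np.zeros((spec.aev_length, n, 3))

    disp = _neighbor_displacements(coords, center, box)
    dist = np.linalg.norm(disp, axis=1)
    mask = (dist < spec.radial_cutoff) & (np.arange(n) != center)
    nb = np.nonzero(mask)[0]
    if nb.size == 0:
        return jac
    sp_idx = np.array([el_index[species[j]] for j in nb])
    d = dist[nb]
    unit = disp[nb] / d[:, None]          # direction center -> neighbor

    # radial derivatives
    gauss = np.exp(-spec.radial_eta[None, :] * (d[:, None] - spec.radial_shifts[None, :]) ** 2)
    fc = cutoff_fn(d, spec.radial_cutoff)
    dfc = cutoff_fn_deriv(d, spec.radial_cutoff)
    dterm_dr = gauss * (
        -2.0 * spec.radial_eta[None, :] * (d[:, None] - spec.radial_shifts[None, :]) * fc[:, None]
        + dfc[:, None]
    )  # (n_nb, M)
    for idx, j in enumerate(nb):
        block = spec.radial_block(int(sp_idx[idx]))
        contrib = dterm_dr[idx][:, None] * unit[idx][None, :]  # (M, 3)
        jac[block, j, :] += contrib
        jac[block, center, :] -= contrib

    # angular derivatives
    amask = d < spec.angular_cutoff
    anb = nb[amask]
    if anb.size < 2:
        return jac
    u = disp[anb]
    du = d[amask]
    sa = sp_idx[amask]
    jj, kk = np.triu_indices(anb.size, k=1)
    uj, uk = u[jj], u[kk]
    rj, rk = du[jj], du[kk]
    cosang = np.einsum("ij,ij->i", uj, uk) / (rj * rk)
    cosang = np.clip(cosang, -1.0 + 1e-10, 1.0 - 1e-10)
    theta = np.arccos(cosang)
    sin_t = np.sqrt(1.0 - cosang**2)

    fcj = cutoff_fn(rj, spec.angular_cutoff)
    fck = cutoff_fn(rk, spec.angular_cutoff)
    dfcj = cutoff_fn_deriv(rj, spec.angular_cutoff)
    dfck = cutoff_fn_deriv(rk, spec.angular_cutoff)

    dth = theta[:, None] - spec.angular_thetas[None, :]
    one_cos = 1.0 + np.cos(dth)
    ang = one_cos ** spec.angular_zeta[None, :]
    ravg = 0.5 * (rj + rk)
    rad = np.exp(-spec.angular_eta[None, :] * (ravg[:, None] - spec.angular_shifts[None, :]) ** 2)
    pref = 2.0 ** (1.0 - spec.angular_zeta)[None, :]
    fcpair = (fcj * fck)[:, None]
    term = pref * ang * rad * fcpair                      # (P, A)

    # partials of the scalar term w.r.t. theta, rj, rk
    dterm_dtheta = pref * rad * fcpair * spec.angular_zeta[None, :] * one_cos ** (
        spec.angular_zeta[None, :] - 1.0) * (-np.sin(dth))
    dgauss = -spec.angular_eta[None, :] * (ravg[:, None] - spec.angular_shifts[None, :]) * rad
    dterm_drj = pref * ang * (dgauss * fcpair + rad * (dfcj * fck)[:, None])
    dterm_drk = pref * ang * (dgauss * fcpair + rad * (fcj * dfck)[:, None])

    # geometric gradients: dcos/dx then dtheta = -dcos/sin
    # cos = (uj.uk)/(rj rk) with uj = r_j - r_i etc.
    inv_rjrk = 1.0 / (rj * rk)
    dcos_duj = uk * inv_rjrk[:, None] - uj * (cosang / rj**2)[:, None]
    dcos_duk = uj * inv_rjrk[:, None] - uk * (cosang / rk**2)[:, None]
    dtheta_duj = -dcos_duj / sin_t[:, None]
    dtheta_duk = -dcos_duk / sin_t[:, None]
    drj_duj = uj / rj[:, None]
    drk_duk = uk / rk[:, None]

    pair_sp = np.stack([np.minimum(sa[jj], sa[kk]), np.maximum(sa[jj], sa[kk])], axis=1)
    aj_atoms = anb[jj]
    ak_atoms = anb[kk]
    for p in range(jj.size):
        block = spec.angular_block((int(pair_sp[p, 0]), int(pair_sp[p, 1])))
        gj = (dterm_dtheta[p][:, None] * dtheta_duj[p][None, :]
              + dterm_drj[p][:, None] * drj_duj[p][None, :])   # (A, 3) wrt r_j
        gk = (dterm_dtheta[p][:, None] * dtheta_duk[p][None, :]
              + dterm_drk[p][:, None] * drk_duk[p][None, :])
        jac[block, aj_atoms[p], :] += gj
        jac[block, ak_atoms[p], :] += gk
        jac[block, center, :] -= gj + gk
    return jac


@dataclass
class LocalEnvDescriptor:
    """Sorted local-environment rows (1/R, x/R^2, y/R^2, z/R^2) per neighbor."""

    rows: np.ndarray            # (n_neighbors, 4)
    neighbor_indices: np.ndarray
    frame: np.ndarray           # (3, 3) local axes as rows


def deepmd_descriptor(
    coords: np.ndarray,
    species: list[str],
    center: int,
    cutoff: float,
    elements: tuple[str, ...] | None = None,
    box: PeriodicBox | None = None,
) -> LocalEnvDescriptor:
    """Local-environment descriptor in a frame built from the two nearest
    neighbors, rows sorted by species then inverse distance (closest first).

    Rotation/translation invariance follows from expressing the neighbor
    coordinates in the local frame; determinism from the index tie-break.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    disp = _neighbor_displacements(coords, center, box)
    dist = np.linalg.norm(disp, axis=1)
    mask = (dist < cutoff) & (np.arange(n) != center)
    nb = np.nonzero(mask)[0]
    if nb.size < 2:
        raise ValueError("local frame needs at least two neighbors within cutoff")

    order_near = nb[np.lexsort((nb, dist[nb]))]
    a, b = order_near[0], order_near[1]
    e1 = disp[a] / dist[a]
    v2 = disp[b] - np.dot(disp[b], e1) * e1
    n2 = np.linalg.norm(v2)
    if n2 < 1e-8:
        raise ValueError("degenerate (collinear) neighbors; cannot build frame")
    e2 = v2 / n2
    e3 = np.cross(e1, e2)
    frame = np.stack([e1, e2, e3])

    if elements is None:
        elements = tuple(sorted(set(species)))
    sp_rank = np.array([elements.index(species[j]) for j in nb])
    invd = 1.0 / dist[nb]
    # species ascending, then inverse distance descending, index tie-break
    order = np.lexsort((nb, -invd, sp_rank))
    nb_sorted = nb[order]
    local = disp[nb_sorted] @ frame.T
    r = dist[nb_sorted]
    rows = np.column_stack([1.0 / r, local / r[:, None] ** 2])
    return LocalEnvDescriptor(rows=rows, neighbor_indices=nb_sorted, frame=frame)
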