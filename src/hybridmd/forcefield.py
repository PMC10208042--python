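"""Reduced polarizable force field.

Energy terms:

* anharmonic bond stretches and angle bends plus harmonic Urey-Bradley 1-3
  distance terms;
* Halgren buffered 14-7 van der Waals with a C^2 switching taper and a
  softcore form for alchemical decoupling;
* periodic electrostatics of point charges and point dipoles by direct
  Ewald summation (real-space erfc kernels, explicit reciprocal k-sum,
  self terms, tinfoil boundary, neutralizing-background correction for
  charged boxes);
* many-body polarization: Thole-damped induced point dipoles solved by a
  diagonally preconditioned conjugate-gradient iteration.

All forces are analytic gradients of the implemented energy; polarization
forces use the converged-variational (envelope) expression, exact at tight
solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .constants import COULOMB
from .neighbors import PairList, brute_force_pairs, build_pair_list, refresh_pair_list
from .system import AtomicSystem, EnergyReport, FFParameters, PeriodicBox, minimum_image

_SQRT_PI = math.sqrt(math.pi)

#: cache of (n-vectors, k-vectors, weights) keyed by box/alpha/kmax
_KVEC_CACHE: dict = {}


def _excluded_keys(params: FFParameters, n: int) -> np.ndarray:
    """Sorted int64 keys of excluded pairs, cached on the parameter object."""
    cached = getattr(params, "_excl_key_cache", None)
    if cached is not None and cached[0] == n:
        return cached[1]
    keys = np.array(sorted(int(a) * n + int(b)
                           for a, b in params.excluded_pairs()), dtype=np.int64)
    params._excl_key_cache = (n, keys)
    return keys


def _excluded_mask(params: FFParameters, n: int, iu, ju) -> np.ndarray:
    keys = _excluded_keys(params, n)
    if keys.size == 0:
        return np.zeros(iu.shape, dtype=bool)
    return np.isin(iu.astype(np.int64) * n + ju, keys, assume_unique=False)


# ---------------------------------------------------------------------------
# settings


@dataclass
class EwaldSettings:
    """Direct Ewald parameters for an orthorhombic box."""

    alpha: float            # A^-1 splitting parameter
    real_cutoff: float      # A
    kmax: int               # integer shell max per axis
    tinfoil: bool = True

    @classmethod
    def auto(cls, box: PeriodicBox, real_cutoff: float = 7.0,
             accuracy: float = 1e-8) -> "EwaldSettings":
        """Choose alpha and kmax so both sums are converged to ``accuracy``."""
        x = 1.0
        while math.erfc(x) > accuracy:
            x += 0.01
        alpha = x / real_cutoff
        kmax_phys = 2.0 * alpha * math.sqrt(max(-math.log(accuracy), 1.0))
        kmax = max(1, int(math.ceil(kmax_phys * np.max(box.edge_lengths) / (2 * np.pi))))
        return cls(alpha=alpha, real_cutoff=real_cutoff, kmax=kmax)

    def validate(self, box: PeriodicBox) -> None:
        if self.real_cutoff > box.min_edge / 2 + 1e-9:
            raise ValueError(
                f"Ewald real-space cutoff {self.real_cutoff} A exceeds half "
                f"the smallest box edge ({box.min_edge / 2:.3f} A)"
            )
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")


@dataclass
class FFSettings:
    """Cutoffs and numerical knobs of the force-field evaluation."""

    vdw_cutoff: float = 12.0
    vdw_switch_width: float = 1.0
    ewald_real_cutoff: float = 7.0
    ewald_accuracy: float = 1e-8
    pol_tolerance: float = 1e-5
    pol_max_iter: int = 200
    softcore_beta: float = 0.7
    softcore_t: int = 5
    neighbor_skin: float = 2.0


@dataclass
class InducedDipoles:
    """Converged induced dipoles and solver diagnostics."""

    mu: np.ndarray            # (n, 3) e*A, zero rows on non-polarizable sites
    residual: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# bonded terms


def _bonded_arrays(params: FFParameters):
    """Vectorized views of the bonded term lists, cached on the parameters."""
    cached = getattr(params, "_bonded_array_cache", None)
    if cached is not None:
        return cached
    b = params.bonds
    a = params.angles
    u = params.urey_bradley
    arrays = {
        "b_ij": np.array([[t.i, t.j] for t in b], dtype=int).reshape(-1, 2),
        "b_par": np.array([[t.r0, t.k, t.cubic, t.quartic] for t in b],
                          dtype=float).reshape(-1, 4),
        "a_ijk": np.array([[t.i, t.j, t.k_atom] for t in a],
                          dtype=int).reshape(-1, 3),
        "a_par": np.array([[t.theta0, t.k, t.cubic, t.quartic] for t in a],
                          dtype=float).reshape(-1, 4),
        "u_ik": np.array([[t.i, t.k_atom] for t in u], dtype=int).reshape(-1, 2),
        "u_par": np.array([[t.d0, t.k] for t in u], dtype=float).reshape(-1, 2),
    }
    params._bonded_array_cache = arrays
    return arrays


def bonded_energy_forces(coords: np.ndarray, params: FFParameters,
                         box: PeriodicBox | None = None) -> EnergyReport:
    """Anharmonic bond/angle plus Urey-Bradley energies and analytic forces."""
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    arr = _bonded_arrays(params)

    def _disp(a, b):
        d = coords[a] - coords[b]
        return minimum_image(d, box) if box is not None else d

    if arr["b_ij"].shape[0]:
        ij = arr["b_ij"]
        r0, k, c3, c4 = arr["b_par"].T
        d = _disp(ij[:, 0], ij[:, 1])
        r = np.linalg.norm(d, axis=1)
        dr = r - r0
        energy += float(np.sum(k * dr**2 * (1.0 + c3 * dr + c4 * dr**2)))
        de = k * (2.0 * dr + 3.0 * c3 * dr**2 + 4.0 * c4 * dr**3)
        f = (-de / r)[:, None] * d
        np.add.at(forces, ij[:, 0], f)
        np.add.at(forces, ij[:, 1], -f)

    if arr["a_ijk"].shape[0]:
        ijk = arr["a_ijk"]
        th0, k, c3, c4 = arr["a_par"].T
        u = _disp(ijk[:, 0], ijk[:, 1])
        v = _disp(ijk[:, 2], ijk[:, 1])
        ru = np.linalg.norm(u, axis=1)
        rv = np.linalg.norm(v, axis=1)
        c = np.einsum("ij,ij->i", u, v) / (ru * rv)
        c = np.clip(c, -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(c)
        dt = theta - th0
        energy += float(np.sum(k * dt**2 * (1.0 + c3 * dt + c4 * dt**2)))
        de = k * (2.0 * dt + 3.0 * c3 * dt**2 + 4.0 * c4 * dt**3)
        sin_t = np.sqrt(1.0 - c * c)
        dc_du = v / (ru * rv)[:, None] - u * (c / ru**2)[:, None]
        dc_dv = u / (ru * rv)[:, None] - v * (c / rv**2)[:, None]
        g = (de / sin_t)[:, None]
        f_i = g * dc_du
        f_k = g * dc_dv
        np.add.at(forces, ijk[:, 0], f_i)
        np.add.at(forces, ijk[:, 2], f_k)
        np.add.at(forces, ijk[:, 1], -(f_i + f_k))

    if arr["u_ik"].shape[0]:
        ik = arr["u_ik"]
        d0, k = arr["u_par"].T
        d = _disp(ik[:, 0], ik[:, 1])
        r = np.linalg.norm(d, axis=1)
        dr = r - d0
        energy += float(np.sum(k * dr**2))
        f = (-2.0 * k * dr / r)[:, None] * d
        np.add.at(forces, ik[:, 0], f)
        np.add.at(forces, ik[:, 1], -f)

    return EnergyReport(components={"bonded": energy}, forces=forces)


# ---------------------------------------------------------------------------
# van der Waals


_DELTA = 0.07
_GAMMA = 0.12


def _combine_vdw(r0i, r0j, epsi, epsj):
    """AMOEBA-style combining: cubic-mean r0, HHG epsilon."""
    r0 = (r0i**3 + r0j**3) / (r0i**2 + r0j**2)
    se = np.sqrt(epsi) + np.sqrt(epsj)
    with np.errstate(invalid="ignore", divide="ignore"):
        eps = np.where(se > 0, 4.0 * epsi * epsj / se**2, 0.0)
    return r0, eps


def _switch(r, r_on, r_off):
    """C^2 quintic taper: 1 below r_on, 0 above r_off."""
    x = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - x**3 * (10.0 - 15.0 * x + 6.0 * x**2)
    ds = -x**2 * (30.0 - 60.0 * x + 30.0 * x**2) / (r_off - r_on)
    ds = np.where((r > r_on) & (r < r_off), ds, 0.0)
    return s, ds


def buffered_14_7(r, r0, eps, lam=1.0, beta=0.7, t=5):
    """Halgren buffered 14-7 pair energy and dE/dr, with optional softcore.

    At lam == 1 the plain buffered form is recovered exactly; for lam < 1
    the buffering denominators gain beta*(1-lam)^2 so the energy stays
    finite down to r = 0, and the whole term is scaled by lam**t.
    """
    rho = r / r0
    b = beta * (1.0 - lam) ** 2
    p = (rho + _DELTA) ** 7 + b
    q = rho**7 + _GAMMA + b
    pref = lam**t * eps * (1.0 + _DELTA) ** 7
    e = pref / p * ((1.0 + _GAMMA) / q - 2.0)
    de_drho = pref * (
        -7.0 * (rho + _DELTA) ** 6 / p**2 * ((1.0 + _GAMMA) / q - 2.0)
        - (1.0 + _GAMMA) * 7.0 * rho**6 / (p * q**2)
    )
    return e, de_drho / r0


def vdw_energy_forces(
    coords: np.ndarray,
    params: FFParameters,
    pairlist: PairList | None,
    settings: FFSettings,
    box: PeriodicBox | None,
    lam_vdw: float = 1.0,
    solute_mask: np.ndarray | None = None,
) -> EnergyReport:
    """Buffered 14-7 van der Waals over the pair list.

    The softcore lambda applies only to solute-environment pairs (the ones
    being decoupled); intra-solute and environment pairs keep lam = 1.
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    if pairlist is None:
        iu, ju = np.triu_indices(n, k=1)
        disp = coords[iu] - coords[ju]
        dist = np.linalg.norm(disp, axis=1)
        cutoff = None
    else:
        mask = pairlist.within(settings.vdw_cutoff)
        iu, ju = pairlist.pairs[mask, 0], pairlist.pairs[mask, 1]
        disp, dist = pairlist.displacements[mask], pairlist.distances[mask]
        cutoff = settings.vdw_cutoff
    if iu.size == 0:
        return EnergyReport(components={"vdw": 0.0}, forces=forces)

    keep = ~_excluded_mask(params, n, iu, ju)
    iu, ju, disp, dist = iu[keep], ju[keep], disp[keep], dist[keep]
    if iu.size == 0:
        return EnergyReport(components={"vdw": 0.0}, forces=forces)

    r0, eps = _combine_vdw(params.vdw_r0[iu], params.vdw_r0[ju],
                           params.vdw_eps[iu], params.vdw_eps[ju])
    if solute_mask is not None and lam_vdw != 1.0:
        cross = solute_mask[iu] != solute_mask[ju]
        lam = np.where(cross, lam_vdw, 1.0)
    else:
        lam = np.ones_like(dist)
    e, de = buffered_14_7(dist, r0, eps, lam,
                          beta=settings.softcore_beta, t=settings.softcore_t)
    if cutoff is not None:
        s, ds = _switch(dist, cutoff - settings.vdw_switch_width, cutoff)
        de = de * s + e * ds
        e = e * s
    energy = float(np.sum(e))
    fpair = (-de / dist)[:, None] * disp
    forces = _scatter_add(n, iu, fpair) - _scatter_add(n, ju, fpair)
    return EnergyReport(components={"vdw": energy}, forces=forces)


# ---------------------------------------------------------------------------
# electrostatics: kernels


def _bn_screened(r, alpha, nmax=3):
    """Ewald real-space kernels B0..Bnmax (erfc-screened 1/r derivatives)."""
    g = 2.0 * alpha / _SQRT_PI * np.exp(-((alpha * r) ** 2))
    b = [erfc(alpha * r) / r]
    for n in range(nmax):
        b.append(((2 * n + 1) * b[-1] + (2.0 * alpha**2) ** n * g) / r**2)
    return b


def _bn_plain(r, nmax=3):
    b = [1.0 / r]
    for n in range(nmax):
        b.append((2 * n + 1) * b[-1] / r**2)
    return b


def _thole_factors(r, alpha_i, alpha_j, a):
    """Thole exponential damping factors and radial derivatives.

    lambda3 damps 1/r^3 terms, lambda5 the 3/r^5 term.  Pairs where either
    site has zero polarizability are left undamped.
    """
    prod = alpha_i * alpha_j
    ok = prod > 0
    s = np.where(ok, a * r**3 / np.sqrt(np.where(ok, prod, 1.0)), np.inf)
    es = np.exp(-np.minimum(s, 50.0))
    l3 = 1.0 - es
    l5 = 1.0 - (1.0 + s) * es
    dl3 = 3.0 * s / r * es
    dl5 = 3.0 * s**2 / r * es
    l3 = np.where(ok, l3, 1.0)
    l5 = np.where(ok, l5, 1.0)
    dl3 = np.where(ok, dl3, 0.0)
    dl5 = np.where(ok, dl5, 0.0)
    return l3, l5, dl3, dl5


@dataclass
class _Kernels:
    """Radial kernels (and derivatives) for charge-dipole pair interactions."""

    kqq: np.ndarray
    dkqq: np.ndarray
    kqd: np.ndarray
    dkqd: np.ndarray
    kd1: np.ndarray
    dkd1: np.ndarray
    kd2: np.ndarray
    dkd2: np.ndarray


def _kernels_screened(r, alpha) -> _Kernels:
    b0, b1, b2, b3 = _bn_screened(r, alpha)
    return _Kernels(b0, -r * b1, b1, -r * b2, b1, -r * b2, b2, -r * b3)


def _kernels_plain(r) -> _Kernels:
    b0, b1, b2, b3 = _bn_plain(r)
    return _Kernels(b0, -r * b1, b1, -r * b2, b1, -r * b2, b2, -r * b3)


def _kernels_erf(r, alpha) -> _Kernels:
    p = _kernels_plain(r)
    s = _kernels_screened(r, alpha)
    return _Kernels(*(getattr(p, f) - getattr(s, f) for f in
                      ("kqq", "dkqq", "kqd", "dkqd", "kd1", "dkd1", "kd2", "dkd2")))


def _apply_thole(k: _Kernels, r, alpha_i, alpha_j, a) -> _Kernels:
    """Subtract the undamped-minus-damped short-range complement from the
    dipole kernels (charge-charge is never damped)."""
    l3, l5, dl3, dl5 = _thole_factors(r, alpha_i, alpha_j, a)
    c3 = (1.0 - l3) / r**3
    dc3 = -dl3 / r**3 - 3.0 * (1.0 - l3) / r**4
    c5 = 3.0 * (1.0 - l5) / r**5
    dc5 = -3.0 * dl5 / r**5 - 15.0 * (1.0 - l5) / r**6
    return _Kernels(
        k.kqq, k.dkqq,
        k.kqd - c3, k.dkqd - dc3,
        k.kd1 - c3, k.dkd1 - dc3,
        k.kd2 - c5, k.dkd2 - dc5,
    )


def _pair_energy_forces(disp, r, qi, qj, di, dj, k: _Kernels):
    """Energy and force-on-i for charge+dipole pairs; disp = r_i - r_j.

    U = qq Kqq + Kqd (qi dj.r - qj di.r) + Kd1 di.dj - Kd2 (di.r)(dj.r)
    """
    dir_dot_j = np.einsum("ij,ij->i", dj, disp)
    dir_dot_i = np.einsum("ij,ij->i", di, disp)
    didj = np.einsum("ij,ij->i", di, dj)
    x = qi * dir_dot_j - qj * dir_dot_i
    u = qi * qj * k.kqq + k.kqd * x + k.kd1 * didj - k.kd2 * dir_dot_i * dir_dot_j
    radial = (qi * qj * k.dkqq + k.dkqd * x + k.dkd1 * didj
              - k.dkd2 * dir_dot_i * dir_dot_j) / r
    grad = radial[:, None] * disp
    grad += k.kqd[:, None] * (qi[:, None] * dj - qj[:, None] * di)
    grad -= k.kd2[:, None] * (dir_dot_j[:, None] * di + dir_dot_i[:, None] * dj)
    return u, -grad


def _pair_field(disp, r, qj, dj, k: _Kernels):
    """Field at i from (q_j, d_j); disp = r_i - r_j."""
    dir_dot_j = np.einsum("ij,ij->i", dj, disp)
    return (qj * k.kqd)[:, None] * disp - k.kd1[:, None] * dj \
        + (k.kd2 * dir_dot_j)[:, None] * disp


def _scatter_add(n: int, idx: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Sum (m, 3) rows into (n, 3) bins; bincount is much faster than ufunc.at."""
    out = np.empty((n, 3))
    for x in range(3):
        out[:, x] = np.bincount(idx, weights=vec[:, x], minlength=n)
    return out


# ---------------------------------------------------------------------------
# electrostatics: workspace


class Electrostatics:
    """One-configuration electrostatics engine (permanent + induced).

    Periodic mode performs direct Ewald summation; non-periodic mode uses
    plain Coulomb kernels over all pairs (used for the isolated solute).
    Thole damping applies to every interaction involving an induced dipole.
    Excluded (1-2/1-3) pairs interact neither through permanent terms nor
    through the permanent field, but mutual induction is kept everywhere
    (each molecule acts as one polarization group).
    """

    def __init__(self, coords, charges, dipoles, polarizabilities, thole_a,
                 excluded,
                 box: PeriodicBox | None,
                 ewald: EwaldSettings | None,
                 pairlist: PairList | None = None,
                 full_mutual_ewald: bool = False):
        self.full_mutual_ewald = full_mutual_ewald
        self.coords = np.asarray(coords, dtype=float)
        self.n = self.coords.shape[0]
        self.q = np.asarray(charges, dtype=float)
        self.p = np.asarray(dipoles, dtype=float)
        self.alpha_pol = np.asarray(polarizabilities, dtype=float)
        self.thole_a = thole_a
        self.box = box
        self.ewald = ewald
        if isinstance(excluded, np.ndarray):
            excl_keys = excluded
        else:
            excl_keys = np.array(
                sorted(int(min(t)) * self.n + int(max(t)) for t in excluded),
                dtype=np.int64)

        if box is not None:
            ewald.validate(box)
            if pairlist is None:
                pairlist = brute_force_pairs(
                    AtomicSystem(species=["H"] * self.n, coordinates=self.coords,
                                 box=box),
                    ewald.real_cutoff)
            mask = pairlist.within(ewald.real_cutoff)
            pi, pj = pairlist.pairs[mask, 0], pairlist.pairs[mask, 1]
            disp, dist = pairlist.displacements[mask], pairlist.distances[mask]
        else:
            pi, pj = np.triu_indices(self.n, k=1)
            disp = self.coords[pi] - self.coords[pj]
            dist = np.linalg.norm(disp, axis=1)

        if excl_keys.size:
            is_excl = np.isin(pi.astype(np.int64) * self.n + pj, excl_keys)
        else:
            is_excl = np.zeros(pi.shape, dtype=bool)

        self.pi, self.pj = pi, pj
        self.disp, self.dist = disp, dist
        self.is_excl = is_excl

        if box is not None:
            a = ewald.alpha
            self.k_scr = _kernels_screened(dist, a)
            self.k_scr_damped = _apply_thole(
                self.k_scr, dist, self.alpha_pol[pi], self.alpha_pol[pj], thole_a)
            # excluded pairs also need the erf complement for removal
            self.k_erf_excl = _kernels_erf(dist[is_excl], a) if is_excl.any() else None
            self._setup_reciprocal()
        else:
            self.k_plain = _kernels_plain(dist)
            self.k_plain_damped = _apply_thole(
                self.k_plain, dist, self.alpha_pol[pi], self.alpha_pol[pj], thole_a)

    # -- reciprocal machinery ------------------------------------------------

    def _setup_reciprocal(self):
        box = self.box
        ew = self.ewald
        L = box.edge_lengths
        key = (tuple(np.round(L, 12)), round(ew.alpha, 12), ew.kmax)
        cached = _KVEC_CACHE.get(key)
        if cached is None:
            rng = np.arange(-ew.kmax, ew.kmax + 1)
            nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
            nvec = np.column_stack([nx.ravel(), ny.ravel(), nz.ravel()])
            kvec = 2.0 * np.pi * nvec / L[None, :]
            k2 = np.einsum("ij,ij->i", kvec, kvec)
            kmax_phys = 2.0 * np.pi * ew.kmax / np.min(L)
            keep = (k2 > 0) & (k2 <= kmax_phys**2 + 1e-12)
            # half space: count each +-k pair once with weight 2
            order = (nvec[:, 0] > 0) | ((nvec[:, 0] == 0) & (nvec[:, 1] > 0)) | (
                (nvec[:, 0] == 0) & (nvec[:, 1] == 0) & (nvec[:, 2] > 0))
            keep &= order
            cached = (nvec[keep], kvec[keep],
                      2.0 * np.exp(-k2[keep] / (4.0 * ew.alpha**2)) / k2[keep])
            if len(_KVEC_CACHE) > 32:
                _KVEC_CACHE.clear()
            _KVEC_CACHE[key] = cached
        self.nvec, self.kvec, self.kweight = cached
        # phases e^{i k.r} via separable per-axis powers
        kmax = ew.kmax
        phases_axis = []
        for ax in range(3):
            base = np.exp(2j * np.pi * self.coords[:, ax] / L[ax])  # (n,)
            tab = np.empty((2 * kmax + 1, self.n), dtype=complex)
            tab[kmax] = 1.0
            for m in range(1, kmax + 1):
                tab[kmax + m] = tab[kmax + m - 1] * base
            tab[:kmax] = np.conj(tab[kmax + 1:][::-1])
            phases_axis.append(tab)
        phase = (phases_axis[0][self.nvec[:, 0] + kmax]
                 * phases_axis[1][self.nvec[:, 1] + kmax])
        phase *= phases_axis[2][self.nvec[:, 2] + kmax]  # (nk, n)
        self.ph_re = np.ascontiguousarray(phase.real)
        self.ph_im = np.ascontiguousarray(phase.imag)
        self.kw_kvec = self.kweight[:, None] * self.kvec  # (nk, 3)
        # symmetric k_x k_y weight table for dipole reciprocal forces
        kx, ky, kz = self.kvec.T
        self.kw_kxy = (self.kweight[:, None]
                       * np.column_stack([kx * kx, ky * ky, kz * kz,
                                          kx * ky, kx * kz, ky * kz]))

    def _structure_factor(self, q, d):
        """S(k) = sum_j (q_j + i k.d_j) e^{i k.r_j}; returns (re, im)."""
        pd = self.ph_re @ d            # (nk, 3)
        qd = self.ph_im @ d
        kd_re = -np.einsum("kx,kx->k", self.kvec, qd)   # -sum_j kd*ph_im
        kd_im = np.einsum("kx,kx->k", self.kvec, pd)    # +sum_j kd*ph_re
        s_re = self.ph_re @ q + kd_re
        s_im = self.ph_im @ q + kd_im
        return s_re, s_im

    def _recip_energy(self, s):
        s_re, s_im = s
        pref = 2.0 * np.pi / self.box.volume
        return pref * float(np.sum(self.kweight * (s_re**2 + s_im**2)))

    def _recip_forces(self, s, q, d):
        """Force from the reciprocal sum, per atom (all real matmuls)."""
        s_re, s_im = s
        pref = 4.0 * np.pi / self.box.volume
        a = s_re[:, None] * self.ph_im - s_im[:, None] * self.ph_re  # (nk, n)
        forces = (a.T @ self.kw_kvec) * q[:, None]
        b = s_re[:, None] * self.ph_re + s_im[:, None] * self.ph_im
        c = b.T @ self.kw_kxy                                        # (n, 6)
        forces[:, 0] += c[:, 0] * d[:, 0] + c[:, 3] * d[:, 1] + c[:, 4] * d[:, 2]
        forces[:, 1] += c[:, 3] * d[:, 0] + c[:, 1] * d[:, 1] + c[:, 5] * d[:, 2]
        forces[:, 2] += c[:, 4] * d[:, 0] + c[:, 5] * d[:, 1] + c[:, 2] * d[:, 2]
        return pref * forces

    def _recip_field(self, s):
        """Field at each site from structure factor s (gradient wrt dipoles)."""
        s_re, s_im = s
        pref = 4.0 * np.pi / self.box.volume
        a = s_re[:, None] * self.ph_im - s_im[:, None] * self.ph_re
        return pref * (a.T @ self.kw_kvec)

    # -- permanent field and induced-dipole matvec ---------------------------

    def permanent_field(self):
        """Field of permanent charges+dipoles at every site (e/A^2 units)."""
        field = np.zeros((self.n, 3))
        inc = ~self.is_excl
        if self.box is not None:
            k = _slice_kernels(self.k_scr_damped, inc)
        else:
            k = _slice_kernels(self.k_plain_damped, inc)
        pi, pj = self.pi[inc], self.pj[inc]
        disp, dist = self.disp[inc], self.dist[inc]
        f_i = _pair_field(disp, dist, self.q[pj], self.p[pj], k)
        f_j = _pair_field(-disp, dist, self.q[pi], self.p[pi], k)
        field += _scatter_add(self.n, pi, f_i)
        field += _scatter_add(self.n, pj, f_j)
        if self.box is not None:
            s_perm = self._structure_factor(self.q, self.p)
            field += self._recip_field(s_perm)
            a = self.ewald.alpha
            field += (4.0 * a**3 / (3.0 * _SQRT_PI)) * self.p
            if self.k_erf_excl is not None:
                pi_e, pj_e = self.pi[self.is_excl], self.pj[self.is_excl]
                de, re = self.disp[self.is_excl], self.dist[self.is_excl]
                f_i = _pair_field(de, re, self.q[pj_e], self.p[pj_e], self.k_erf_excl)
                f_j = _pair_field(-de, re, self.q[pi_e], self.p[pi_e], self.k_erf_excl)
                np.add.at(field, pi_e, -f_i)
                np.add.at(field, pj_e, -f_j)
        return field

    def induced_field(self, mu):
        """Field at every site from induced dipoles mu (mutual coupling).

        By default mutual polarization is restricted to the real-space
        Thole-damped tensor: the reciprocal-space coupling between induced
        dipoles is dropped (a documented approximation that keeps every CG
        iteration free of k-space work).  The permanent field that drives
        the induction always retains the full Ewald treatment; with
        ``full_mutual_ewald`` the mutual coupling does too.
        """
        k = self.k_scr_damped if self.box is not None else self.k_plain_damped
        zeros = np.zeros(self.pi.shape[0])
        f_i = _pair_field(self.disp, self.dist, zeros, mu[self.pj], k)
        f_j = _pair_field(-self.disp, self.dist, zeros, mu[self.pi], k)
        field = _scatter_add(self.n, self.pi, f_i) \
            + _scatter_add(self.n, self.pj, f_j)
        if self.box is not None and self.full_mutual_ewald:
            s_ind = self._structure_factor(np.zeros(self.n), mu)
            field += self._recip_field(s_ind)
            a = self.ewald.alpha
            field += (4.0 * a**3 / (3.0 * _SQRT_PI)) * mu
        return field

    def solve_induced(self, tolerance=1e-5, max_iter=200, mu_guess=None) -> InducedDipoles:
        """Preconditioned CG on (alpha^-1 - T) mu = E_perm.

        The preconditioner is the diagonal alpha; non-polarizable sites are
        held at zero.  Residual is the 2-norm over polarizable components.
        """
        pol = self.alpha_pol > 0
        if not pol.any():
            return InducedDipoles(np.zeros((self.n, 3)), 0.0, 0, True)
        e_perm = self.permanent_field()

        def matvec(mu_full):
            out = mu_full / np.where(pol, self.alpha_pol, 1.0)[:, None] \
                - self.induced_field(mu_full)
            out[~pol] = 0.0
            return out

        mu = np.zeros((self.n, 3)) if mu_guess is None else mu_guess.copy()
        mu[~pol] = 0.0
        b = e_perm.copy()
        b[~pol] = 0.0
        r = b - matvec(mu)
        r[~pol] = 0.0
        z = r * np.where(pol, self.alpha_pol, 0.0)[:, None]
        d = z.copy()
        rz = float(np.sum(r * z))
        res = float(np.linalg.norm(r))
        it = 0
        while res > tolerance and it < max_iter:
            ad = matvec(d)
            denom = float(np.sum(d * ad))
            if denom == 0.0:
                break
            step = rz / denom
            mu = mu + step * d
            r = r - step * ad
            res = float(np.linalg.norm(r))
            z = r * np.where(pol, self.alpha_pol, 0.0)[:, None]
            rz_new = float(np.sum(r * z))
            d = z + (rz_new / rz) * d
            rz = rz_new
            it += 1
        if res > tolerance:
            raise RuntimeError(
                f"induced-dipole PCG failed to converge: residual {res:.3e} "
                f"after {it} iterations (tolerance {tolerance:.1e})"
            )
        return InducedDipoles(mu=mu, residual=res, iterations=it, converged=True)

    # -- energies and forces -------------------------------------------------

    def _real_channel(self, q1, d1, q2, d2, kernels, mask):
        """Sum real-space pair energies/forces for given per-site sources."""
        pi, pj = self.pi[mask], self.pj[mask]
        disp, dist = self.disp[mask], self.dist[mask]
        k = _slice_kernels(kernels, mask) if kernels.kqq.shape[0] == self.pi.shape[0] \
            else kernels
        u, f_i = _pair_energy_forces(disp, dist, q1[pi], q2[pj], d1[pi], d2[pj], k)
        forces = _scatter_add(self.n, pi, f_i) - _scatter_add(self.n, pj, f_i)
        return float(np.sum(u)), forces

    def energy_forces(self, mu: np.ndarray):
        """Total electrostatic energy/forces at converged mu, plus the
        permanent-only energy for the component breakdown (kcal/mol)."""
        n = self.n
        d_tot = self.p + mu
        inc = ~self.is_excl
        pol = self.alpha_pol > 0
        u_self_ind = 0.5 * float(
            np.sum(mu[pol] ** 2 / self.alpha_pol[pol, None])
        )
        if self.box is None:
            u_tot, f_tot = self._real_channel(self.q, d_tot, self.q, d_tot,
                                              self.k_plain_damped, inc)
            u_pp_d, f_pp_d = self._real_channel(self.q, self.p, self.q, self.p,
                                                self.k_plain_damped, inc)
            u_pp, f_pp = self._real_channel(self.q, self.p, self.q, self.p,
                                            self.k_plain, inc)
            u = u_tot - u_pp_d + u_pp + u_self_ind
            f = f_tot - f_pp_d + f_pp
            u_perm = u_pp
            f_sum = f
            if self.is_excl.any():
                zq = np.zeros(n)
                u_ii, f_ii = self._real_channel(zq, mu, zq, mu,
                                                self.k_plain_damped, self.is_excl)
                u += u_ii
                f_sum = f_sum + f_ii
            return (u_perm * COULOMB, (u - u_perm) * COULOMB,
                    f_sum * COULOMB)

        a = self.ewald.alpha
        # real space, non-excluded pairs
        u_tot, f_tot = self._real_channel(self.q, d_tot, self.q, d_tot,
                                          self.k_scr_damped, inc)
        u_pp_d, f_pp_d = self._real_channel(self.q, self.p, self.q, self.p,
                                            self.k_scr_damped, inc)
        u_pp, f_pp = self._real_channel(self.q, self.p, self.q, self.p,
                                        self.k_scr, inc)
        u_real = u_tot - u_pp_d + u_pp
        f_real = f_tot - f_pp_d + f_pp
        u_real_pp = u_pp
        f_real_pp = f_pp

        # excluded pairs: remove erf-complement of (q, d_tot) interactions,
        # restore the induced-induced part (erf + screened damped)
        u_excl = u_excl_pp = 0.0
        f_excl = np.zeros((n, 3))
        f_excl_pp = np.zeros((n, 3))
        if self.is_excl.any():
            zq = np.zeros(n)
            u1, f1 = self._real_channel(self.q, d_tot, self.q, d_tot,
                                        self.k_erf_excl, self.is_excl)
            u2, f2 = self._real_channel(zq, mu, zq, mu,
                                        self.k_erf_excl, self.is_excl)
            u3, f3 = self._real_channel(zq, mu, zq, mu,
                                        self.k_scr_damped, self.is_excl)
            u_excl = -u1 + u2 + u3
            f_excl = -f1 + f2 + f3
            upp, fpp = self._real_channel(self.q, self.p, self.q, self.p,
                                          self.k_erf_excl, self.is_excl)
            u_excl_pp = -upp
            f_excl_pp = -fpp

        # reciprocal; in the (default) real-space-restricted mutual mode
        # the induced-induced k-space and self terms are removed to stay
        # consistent with the solve
        s_perm = self._structure_factor(self.q, self.p)
        s_ind = self._structure_factor(np.zeros(n), mu)
        s_tot = (s_perm[0] + s_ind[0], s_perm[1] + s_ind[1])
        u_rec = self._recip_energy(s_tot)
        f_rec = self._recip_forces(s_tot, self.q, d_tot)
        u_self_ind_ewald = 0.0
        if not self.full_mutual_ewald:
            u_rec -= self._recip_energy(s_ind)
            f_rec = f_rec - self._recip_forces(s_ind, np.zeros(n), mu)
            u_self_ind_ewald = (2.0 * a**3 / (3.0 * _SQRT_PI)
                                * float(np.sum(mu**2)))
        u_rec_pp = self._recip_energy(s_perm)

        u_self = -a / _SQRT_PI * float(np.sum(self.q**2)) \
            - 2.0 * a**3 / (3.0 * _SQRT_PI) * float(np.sum(d_tot**2)) \
            + u_self_ind_ewald
        u_self_pp = -a / _SQRT_PI * float(np.sum(self.q**2)) \
            - 2.0 * a**3 / (3.0 * _SQRT_PI) * float(np.sum(self.p**2))
        q_tot = float(np.sum(self.q))
        u_bg = -np.pi * q_tot**2 / (2.0 * a**2 * self.box.volume)

        u_total = u_real + u_excl + u_rec + u_self + u_bg + u_self_ind
        u_perm = u_real_pp + u_excl_pp + u_rec_pp + u_self_pp + u_bg
        forces = f_real + f_excl + f_rec
        return u_perm * COULOMB, (u_total - u_perm) * COULOMB, forces * COULOMB


def _slice_kernels(k: _Kernels, mask) -> _Kernels:
    return _Kernels(*(getattr(k, f)[mask] for f in
                      ("kqq", "dkqq", "kqd", "dkqd", "kd1", "dkd1", "kd2", "dkd2")))


def polarization_energy(mu: np.ndarray, e_perm: np.ndarray) -> float:
    """Variational polarization energy -1/2 sum mu.E_perm, in kcal/mol."""
    return -0.5 * float(np.sum(mu * e_perm)) * COULOMB


def short_range_nonbonded(
    system: AtomicSystem,
    settings: FFSettings,
    switch_r: float = 7.0,
    switch_width: float = 1.0,
    lam_ele: float = 1.0,
    lam_vdw: float = 1.0,
    solute_mask: np.ndarray | None = None,
    pairlist: PairList | None = None,
) -> EnergyReport:
    """Short-range non-bonded forces for the RESPA1 mid level.

    Buffered 14-7 van der Waals plus erfc-screened charge-charge
    electrostatics, both tapered to zero at ``switch_r`` by a C^2 switch.
    This is an approximation of the short-range physics by construction:
    the slow level is defined by subtraction from the full potential, so
    the split remains exact.
    """
    params = system.parameters
    coords = system.coordinates
    n = system.n_atoms
    box = system.box
    if pairlist is None:
        pairlist = brute_force_pairs(system, switch_r)
    mask = pairlist.within(switch_r)
    iu, ju = pairlist.pairs[mask, 0], pairlist.pairs[mask, 1]
    disp, dist = pairlist.displacements[mask], pairlist.distances[mask]
    forces = np.zeros((n, 3))
    if iu.size == 0:
        return EnergyReport(components={"short_range": 0.0}, forces=forces)
    keep = ~_excluded_mask(params, n, iu, ju)
    iu, ju, disp, dist = iu[keep], ju[keep], disp[keep], dist[keep]

    q = params.charges.copy()
    if solute_mask is not None and lam_ele != 1.0:
        q[solute_mask] *= lam_ele

    r0, eps = _combine_vdw(params.vdw_r0[iu], params.vdw_r0[ju],
                           params.vdw_eps[iu], params.vdw_eps[ju])
    if solute_mask is not None and lam_vdw != 1.0:
        cross = solute_mask[iu] != solute_mask[ju]
        lam = np.where(cross, lam_vdw, 1.0)
    else:
        lam = np.ones_like(dist)
    e_vdw, de_vdw = buffered_14_7(dist, r0, eps, lam,
                                  beta=settings.softcore_beta,
                                  t=settings.softcore_t)
    alpha = EwaldSettings.auto(box, settings.ewald_real_cutoff,
                               settings.ewald_accuracy).alpha
    b0 = erfc(alpha * dist) / dist
    db0 = -(b0 + 2.0 * alpha / _SQRT_PI * np.exp(-((alpha * dist) ** 2))) / dist
    e_ele = COULOMB * q[iu] * q[ju] * b0
    de_ele = COULOMB * q[iu] * q[ju] * db0

    e = e_vdw + e_ele
    de = de_vdw + de_ele
    s, ds = _switch(dist, switch_r - switch_width, switch_r)
    de = de * s + e * ds
    e = e * s
    fpair = (-de / dist)[:, None] * disp
    np.add.at(forces, iu, fpair)
    np.add.at(forces, ju, -fpair)
    return EnergyReport(components={"short_range": float(np.sum(e))},
                        forces=forces)


# ---------------------------------------------------------------------------
# full force-field evaluation


class ForceField:
    """Evaluator bundling bonded, van der Waals and electrostatic terms.

    Keeps an internal neighbor list with displacement-triggered rebuilds so
    repeated evaluations along a trajectory stay cheap.
    """

    def __init__(self, settings: FFSettings | None = None):
        self.settings = settings or FFSettings()
        self._pairlist: PairList | None = None
        self._mu_guess: np.ndarray | None = None

    def _get_pairlist(self, system: AtomicSystem, cutoff: float) -> PairList:
        s = self.settings
        if (self._pairlist is None
                or self._pairlist.cutoff != cutoff
                or self._pairlist.build_coordinates.shape[0] != system.n_atoms):
            self._pairlist = build_pair_list(system, cutoff, s.neighbor_skin)
        else:
            self._pairlist = refresh_pair_list(self._pairlist, system)
        return self._pairlist

    def energy_forces(
        self,
        system: AtomicSystem,
        lam_ele: float = 1.0,
        lam_vdw: float = 1.0,
        solute_mask: np.ndarray | None = None,
        periodic: bool = True,
        pol_tolerance: float | None = None,
        reuse_mu: bool = False,
    ) -> EnergyReport:
        """Component-resolved energy and analytic forces.

        ``lam_ele`` scales the charges, permanent dipoles and
        polarizabilities of solute atoms (annihilation); ``lam_vdw`` drives
        the softcore on solute-environment van der Waals pairs.  With
        ``periodic=False`` the system is treated as an isolated cluster
        (no images, no cutoffs) — the mode used for the subtracted
        solute term of the hybrid potential.
        """
        params = system.parameters
        if params is None:
            raise ValueError("system has no force-field parameters")
        s = self.settings
        coords = system.coordinates
        n = system.n_atoms
        box = system.box if periodic else None

        q = params.charges.copy()
        p = params.dipoles.copy()
        alpha_pol = params.polarizabilities.copy()
        if solute_mask is not None and lam_ele != 1.0:
            q[solute_mask] *= lam_ele
            p[solute_mask] *= lam_ele
            alpha_pol[solute_mask] *= lam_ele

        report = EnergyReport.zero(n)
        report.add(bonded_energy_forces(coords, params, box))

        if box is not None:
            cutoff = max(s.vdw_cutoff, s.ewald_real_cutoff)
            if cutoff + s.neighbor_skin > box.min_edge / 2:
                raise ValueError(
                    f"cutoff+skin {cutoff + s.neighbor_skin:.2f} A exceeds half "
                    f"box edge {box.min_edge / 2:.2f} A; reduce the cutoffs"
                )
            pairlist = self._get_pairlist(system, cutoff)
            ewald = EwaldSettings.auto(box, s.ewald_real_cutoff, s.ewald_accuracy)
        else:
            pairlist = None
            ewald = None

        report.add(vdw_energy_forces(coords, params, pairlist, s, box,
                                     lam_vdw=lam_vdw, solute_mask=solute_mask))

        elec = Electrostatics(coords, q, p, alpha_pol, params.thole_a,
                              _excluded_keys(params, n), box, ewald, pairlist)
        tol = pol_tolerance if pol_tolerance is not None else s.pol_tolerance
        guess = self._mu_guess if (reuse_mu and self._mu_guess is not None
                                   and self._mu_guess.shape[0] == n) else None
        induced = elec.solve_induced(tolerance=tol, max_iter=s.pol_max_iter,
                                     mu_guess=guess)
        if reuse_mu:
            self._mu_guess = induced.mu
        u_perm, u_pol, f_elec = elec.energy_forces(induced.mu)
        report.components["elec_perm"] = report.components.get("elec_perm", 0.0) + u_perm
        report.components["polarization"] = report.components.get("polarization", 0.0) + u_pol
        report.forces = report.forces + f_elec
        return report
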