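import numpy as np
import pytest

from hybridmd.constants import COULOMB
from hybridmd.forcefield import (Electrostatics, EwaldSettings, FFSettings,
                                 ForceField, bonded_energy_forces,
                                 buffered_14_7, short_range_nonbonded)
from hybridmd.system import (AtomicSystem, BondTerm, FFParameters,
                             PeriodicBox, UreyBradleyTerm)
from hybridmd.synthetic import generate_water_box


def _random_params(rng, n, pol=True, dip=True):
    return FFParameters(
        charges=rng.normal(scale=0.3, size=n),
        dipoles=rng.normal(scale=0.05, size=(n, 3)) if dip else np.zeros((n, 3)),
        polarizabilities=rng.uniform(0.3, 1.0, size=n) if pol else np.zeros(n),
        vdw_r0=np.full(n, 3.2),
        vdw_eps=np.full(n, 0.05),
    )


class TestBondedTerms:
    def test_equilibrium_geometry_zero(self):
        system = generate_water_box(1, seed=0)
        # rebuild ideal geometry exactly at the equilibrium values
        from hybridmd.synthetic import _water_geometry
        system.coordinates = _water_geometry() + 5.0
        rep = bonded_energy_forces(system.coordinates, system.parameters)
        assert abs(rep.total) < 1e-18
        assert np.abs(rep.forces).max() < 1e-12

    def test_single_harmonic_bond_value(self):
        params = FFParameters(charges=[0, 0], dipoles=np.zeros((2, 3)),
                              polarizabilities=[0, 0], vdw_r0=[3, 3],
                              vdw_eps=[0, 0],
                              bonds=[BondTerm(0, 1, 1.0, 400.0)])
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        rep = bonded_energy_forces(coords, params)
        assert abs(rep.total - 4.0) < 1e-10  # k (dr)^2 = 400 * 0.01

    def test_forces_match_finite_differences(self):
        rng = np.random.default_rng(0)
        system = generate_water_box(1, seed=0)
        system.coordinates += rng.normal(scale=0.05, size=(3, 3))
        rep = bonded_energy_forces(system.coordinates, system.parameters)
        h = 1e-6
        for a in range(3):
            for x in range(3):
                cp = system.coordinates.copy(); cp[a, x] += h
                cm = system.coordinates.copy(); cm[a, x] -= h
                fd = -(bonded_energy_forces(cp, system.parameters).total
                       - bonded_energy_forces(cm, system.parameters).total) / (2 * h)
                assert abs(fd - rep.forces[a, x]) < 1e-7 * max(
                    1.0, abs(rep.forces[a, x]))


class TestBuffered147:
    def test_well_depth_at_r0(self):
        # algebraic identity of the buffered form: E(r0) = -eps exactly
        e, de = buffered_14_7(np.array([3.5]), np.array([3.5]),
                              np.array([0.11]))
        assert abs(e[0] + 0.11) < 1e-14
        # derivative agrees with finite differences
        h = 1e-6
        ep, _ = buffered_14_7(np.array([3.5 + h]), np.array([3.5]),
                              np.array([0.11]))
        em, _ = buffered_14_7(np.array([3.5 - h]), np.array([3.5]),
                              np.array([0.11]))
        assert abs((ep[0] - em[0]) / (2 * h) - de[0]) < 1e-8

    def test_decoupled_lambda_zero(self):
        e, _ = buffered_14_7(np.array([3.0]), np.array([3.5]),
                             np.array([0.11]), lam=0.0)
        assert e[0] == 0.0

    def test_softcore_finite_at_contact(self):
        e, de = buffered_14_7(np.array([1e-10]), np.array([3.5]),
                              np.array([0.11]), lam=0.5)
        assert np.isfinite(e[0]) and np.isfinite(de[0])

    def test_lambda_one_recovers_plain_form(self):
        r = np.linspace(2.0, 6.0, 20)
        plain, _ = buffered_14_7(r, np.full_like(r, 3.5), np.full_like(r, 0.1))
        soft, _ = buffered_14_7(r, np.full_like(r, 3.5), np.full_like(r, 0.1),
                                lam=1.0, beta=0.7, t=5)
        np.testing.assert_array_equal(plain, soft)


class TestEwald:
    def test_madelung_constant_rock_salt(self):
        a = 3.0
        coords = np.array([(i, j, k) for i in range(2) for j in range(2)
                           for k in range(2)], float) * a
        q = np.array([(-1.0) ** (i + j + k) for i in range(2)
                      for j in range(2) for k in range(2)])
        box = PeriodicBox([2 * a] * 3)
        ew = EwaldSettings(alpha=1.6, real_cutoff=2.99, kmax=14)
        el = Electrostatics(coords, q, np.zeros((8, 3)), np.zeros(8), 0.39,
                            set(), box, ew)
        up, upol, f = el.energy_forces(np.zeros((8, 3)))
        madelung = -(up / 4) * a / COULOMB
        assert abs(madelung - 1.7475645946) / 1.7475645946 < 1e-4
        assert np.abs(f).max() < 1e-10  # lattice is an equilibrium

    def test_alpha_independence(self):
        rng = np.random.default_rng(2)
        n = 8
        box = PeriodicBox([30.0] * 3)
        coords = rng.uniform(0, 30, size=(n, 3))
        params = _random_params(rng, n)
        ref = None
        for alpha in (0.3, 0.4, 0.5):
            kmax = int(np.ceil(2 * alpha * np.sqrt(23) * 30 / (2 * np.pi))) + 1
            ew = EwaldSettings(alpha=alpha, real_cutoff=13.9, kmax=kmax)
            el = Electrostatics(coords, params.charges, params.dipoles,
                                params.polarizabilities, 0.39, set(), box, ew)
            mu = el.solve_induced(tolerance=1e-10, max_iter=500).mu
            u = sum(el.energy_forces(mu)[:2])
            if ref is None:
                ref = u
            else:
                assert abs(u - ref) / abs(ref) < 1e-6

    def test_isolated_pair_matches_coulomb(self):
        box = PeriodicBox([60.0] * 3)
        coords = np.array([[30.0, 30.0, 30.0], [33.0, 30.0, 30.0]])
        q = np.array([1.0, -1.0])
        ew = EwaldSettings.auto(box, real_cutoff=12.0, accuracy=1e-9)
        el = Electrostatics(coords, q, np.zeros((2, 3)), np.zeros(2), 0.39,
                            set(), box, ew)
        up, _, _ = el.energy_forces(np.zeros((2, 3)))
        exact = -COULOMB / 3.0
        assert abs(up - exact) / abs(exact) < 1e-3

    def test_net_charge_background_keeps_alpha_independence(self):
        rng = np.random.default_rng(3)
        n = 4
        box = PeriodicBox([30.0] * 3)
        coords = rng.uniform(0, 30, size=(n, 3))
        q = np.array([1.0, 1.0, -1.0, 0.5])  # net +1.5
        vals = []
        for alpha in (0.35, 0.5):
            kmax = int(np.ceil(2 * alpha * np.sqrt(23) * 30 / (2 * np.pi))) + 1
            ew = EwaldSettings(alpha=alpha, real_cutoff=13.9, kmax=kmax)
            el = Electrostatics(coords, q, np.zeros((n, 3)), np.zeros(n),
                                0.39, set(), box, ew)
            vals.append(el.energy_forces(np.zeros((n, 3)))[0])
        assert abs(vals[0] - vals[1]) / abs(vals[0]) < 1e-6


class TestInducedDipoles:
    def test_single_site_responds_as_alpha_e(self):
        # one polarizable site next to one fixed charge: mu = alpha E
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        q = np.array([0.5, 0.0])
        alpha = np.array([0.0, 1.2])
        el = Electrostatics(coords, q, np.zeros((2, 3)), alpha, 0.39,
                            set(), None, None)
        sol = el.solve_induced(tolerance=1e-12)
        e_field = el.permanent_field()[1]
        np.testing.assert_allclose(sol.mu[1], 1.2 * e_field, atol=1e-10)

    def test_matches_dense_solve(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = int(rng.integers(2, 30))
            coords = rng.uniform(0, 12, size=(n, 3))
            # keep sites apart
            coords = coords[np.argsort(coords[:, 0])]
            coords[:, 0] += np.arange(n) * 1.2
            params = _random_params(rng, n)
            el = Electrostatics(coords, params.charges, params.dipoles,
                                params.polarizabilities, 0.39, set(),
                                None, None)
            sol = el.solve_induced(tolerance=1e-5)
            # dense operator built column by column from the same matvec
            def matvec(m):
                return (m / params.polarizabilities[:, None]
                        - el.induced_field(m))
            a_mat = np.zeros((3 * n, 3 * n))
            for c in range(3 * n):
                unit = np.zeros((n, 3))
                unit[c // 3, c % 3] = 1.0
                a_mat[:, c] = matvec(unit).ravel()
            mu_dense = np.linalg.solve(a_mat, el.permanent_field().ravel())
            resid = np.linalg.norm(
                a_mat @ sol.mu.ravel() - el.permanent_field().ravel())
            assert resid <= 1e-5
            assert np.abs(sol.mu.ravel() - mu_dense).max() < 1e-5

    def test_zero_polarizability_gives_zero(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 10, size=(5, 3))
        params = _random_params(rng, 5, pol=False)
        el = Electrostatics(coords, params.charges, params.dipoles,
                            np.zeros(5), 0.39, set(), None, None)
        sol = el.solve_induced()
        assert np.all(sol.mu == 0.0)
        _, upol, _ = el.energy_forces(sol.mu)
        assert upol == 0.0


class TestPolarizationEnergy:
    def test_point_charge_plus_site_closed_form(self):
        # field of charge q at distance r: E = q/r^2; U = -1/2 alpha E^2
        q, r, alpha = 0.5, 4.0, 1.2
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        el = Electrostatics(coords, np.array([q, 0.0]), np.zeros((2, 3)),
                            np.array([0.0, alpha]), 0.39, set(), None, None)
        sol = el.solve_induced(tolerance=1e-12)
        _, upol, _ = el.energy_forces(sol.mu)
        expected = -0.5 * alpha * (q / r**2) ** 2 * COULOMB
        assert abs(upol - expected) < 1e-10

    def test_polarization_energy_is_nonpositive(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = int(rng.integers(3, 10))
            coords = rng.uniform(0, 14, size=(n, 3))
            coords[:, 0] += np.arange(n) * 1.4
            params = _random_params(rng, n, dip=False)
            el = Electrostatics(coords, params.charges, params.dipoles,
                                params.polarizabilities, 0.39, set(),
                                None, None)
            sol = el.solve_induced(tolerance=1e-10)
            _, upol, _ = el.energy_forces(sol.mu)
            assert upol <= 1e-12


class TestFullEvaluation:
    def test_component_sum_identity(self, water64_settings):
        system = generate_water_box(27, seed=2)
        ff = ForceField(FFSettings(vdw_cutoff=4.2, ewald_real_cutoff=4.2,
                                   neighbor_skin=0.3))
        rep = ff.energy_forces(system)
        assert abs(rep.total - sum(rep.components.values())) < 1e-10

    def test_net_force_zero_periodic(self):
        system = generate_water_box(12, seed=3)
        ff = ForceField(FFSettings(vdw_cutoff=3.0, ewald_real_cutoff=3.0,
                                   neighbor_skin=0.2))
        rep = ff.energy_forces(system)
        assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8

    def test_empty_region_zero(self):
        # a parameterless system region evaluates to nothing
        params = FFParameters(charges=[], dipoles=np.zeros((0, 3)),
                              polarizabilities=[], vdw_r0=np.ones(0) + 3,
                              vdw_eps=[])
        assert params.n_atoms == 0

    def test_forces_match_fd_all_terms_periodic(self):
        rng = np.random.default_rng(7)
        n = 6
        box = PeriodicBox([14.0] * 3)
        coords = rng.uniform(0, 14, size=(n, 3))
        coords[:, 0] += np.arange(n) * 0.7
        params = _random_params(rng, n)
        params.bonds = [BondTerm(0, 1, 2.0, 50.0, -2.0, 3.0)]
        params.urey_bradley = [UreyBradleyTerm(0, 2, 3.0, 5.0)]
        system = AtomicSystem(species=["O"] * n, coordinates=coords, box=box,
                              parameters=params)
        st = FFSettings(vdw_cutoff=6.0, ewald_real_cutoff=6.0,
                        ewald_accuracy=1e-9, pol_tolerance=1e-11,
                        neighbor_skin=0.5)
        rep = ForceField(st).energy_forces(system)
        h = 1e-5
        fmax = np.abs(rep.forces).max()
        for a in range(n):
            for x in range(3):
                sp = system.copy(); sp.coordinates[a, x] += h
                sm = system.copy(); sm.coordinates[a, x] -= h
                fd = -(ForceField(st).energy_forces(sp).total
                       - ForceField(st).energy_forces(sm).total) / (2 * h)
                assert abs(fd - rep.forces[a, x]) / fmax < 1e-6


class TestShortRangeSplit:
    def test_degenerate_switch_covers_everything_smooth(self):
        system = generate_water_box(16, seed=4)
        st = FFSettings(vdw_cutoff=3.5, ewald_real_cutoff=3.5,
                        neighbor_skin=0.2)
        rep = short_range_nonbonded(system, st, switch_r=3.5, switch_width=1.0)
        assert np.isfinite(rep.total)
        assert np.abs(rep.forces.sum(axis=0)).max() < 1e-9

    def test_forces_match_fd(self):
        system = generate_water_box(16, seed=5)
        st = FFSettings(vdw_cutoff=3.5, ewald_real_cutoff=3.5,
                        neighbor_skin=0.2)
        rep = short_range_nonbonded(system, st, switch_r=3.2, switch_width=0.8)
        h = 1e-5
        fmax = max(np.abs(rep.forces).max(), 1.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = int(rng.integers(system.n_atoms))
            x = int(rng.integers(3))
            sp = system.copy(); sp.coordinates[a, x] += h
            sm = system.copy(); sm.coordinates[a, x] -= h
            fd = -(short_range_nonbonded(sp, st, 3.2, 0.8).total
                   - short_range_nonbonded(sm, st, 3.2, 0.8).total) / (2 * h)
            assert abs(fd - rep.forces[a, x]) / fmax < 1e-6
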