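import numpy as np
import pytest
from scipy.stats import kstest

from hybridmd.constants import INTERNAL_PER_KCAL, KB, kinetic_energy
from hybridmd.dynamics import (ForceSplit, IntegratorConfig, baoab_step,
                               berendsen_scale, bussi_rescale, make_rng,
                               respa1_step, respa_step, run_md,
                               velocity_verlet_step)
from hybridmd.system import (AtomicSystem, EnergyReport, FFParameters,
                             PeriodicBox, draw_maxwell_boltzmann,
                             instantaneous_temperature)


def _oscillator(k=1.0, mass=12.011):
    """1-D harmonic oscillator as a force provider on atom 0, x-axis."""
    def provider(system):
        f = np.zeros_like(system.coordinates)
        x = system.coordinates[0, 0]
        f[0, 0] = -k * x
        return EnergyReport(components={"harm": 0.5 * k * x**2}, forces=f)
    return provider


def _single_atom(x0=1.0):
    system = AtomicSystem(species=["C"], coordinates=[[x0, 0.0, 0.0]],
                          box=PeriodicBox([100.0] * 3))
    return system


def _zero_provider(system):
    return EnergyReport(components={}, forces=np.zeros_like(system.coordinates))


class TestVelocityVerlet:
    def test_zero_force_uniform_drift(self):
        system = _single_atom()
        system.velocities[0] = [0.1, 0.0, 0.0]
        velocity_verlet_step(system, _zero_provider, 2.0)
        np.testing.assert_allclose(system.coordinates[0], [1.2, 0, 0],
                                   atol=1e-14)

    def test_oscillator_energy_conservation(self):
        k = 1.0
        system = _single_atom(1.0)
        provider = _oscillator(k)
        period = 2 * np.pi / np.sqrt(k * INTERNAL_PER_KCAL / system.masses[0])
        dt = period / 100.0
        f = None
        energies = []
        for i in range(10_000):
            f = velocity_verlet_step(system, provider, dt, forces=f)
            if i % 500 == 0:
                e = (0.5 * k * system.coordinates[0, 0] ** 2
                     + kinetic_energy(system.masses, system.velocities))
                energies.append(e)
        drift = max(abs(e - energies[0]) for e in energies) / abs(energies[0])
        assert drift < 1e-4

    def test_time_reversibility(self):
        system = _single_atom(0.7)
        provider = _oscillator(2.0)
        f = None
        for _ in range(50):
            f = velocity_verlet_step(system, provider, 0.5, forces=f)
        system.velocities *= -1.0
        f = None
        for _ in range(50):
            f = velocity_verlet_step(system, provider, 0.5, forces=f)
        assert abs(system.coordinates[0, 0] - 0.7) < 1e-10

    def test_nonfinite_force_halts(self):
        def bad(system):
            return EnergyReport(components={},
                                forces=np.full_like(system.coordinates, np.nan))
        with pytest.raises(FloatingPointError):
            velocity_verlet_step(_single_atom(), bad, 0.5)


class TestBAOAB:
    def test_gamma_zero_reduces_to_verlet(self):
        a, b = _single_atom(0.9), _single_atom(0.9)
        pa, pb = _oscillator(), _oscillator()
        rng = make_rng(0)
        fa = fb = None
        for _ in range(100):
            fa = velocity_verlet_step(a, pa, 0.5, forces=fa)
            fb = baoab_step(b, pb, 0.5, 300.0, 0.0, rng, forces=fb)
        assert abs(a.coordinates[0, 0] - b.coordinates[0, 0]) < 1e-12

    def test_oscillator_equipartition(self):
        k = 5.0
        system = _single_atom(0.0)
        provider = _oscillator(k)
        rng = make_rng(3)
        f = None
        pots = []
        for i in range(60_000):
            f = baoab_step(system, provider, 1.0, 300.0, 0.05, rng, forces=f)
            if i > 5000 and i % 10 == 0:
                pots.append(0.5 * k * system.coordinates[0, 0] ** 2)
        mean_pot = np.mean(pots)
        target = 0.5 * KB * 300.0
        sem = np.std(pots) / np.sqrt(len(pots) / 50)  # crude decorrelation
        assert abs(mean_pot - target) < 3 * max(sem, 0.01 * target)

    def test_fixed_seed_bitwise_reproducible(self):
        def run():
            system = _single_atom(0.4)
            rng = make_rng(7)
            f = None
            for _ in range(200):
                f = baoab_step(system, _oscillator(), 0.5, 300.0, 0.02, rng,
                               forces=f)
            return system.coordinates.copy()
        np.testing.assert_array_equal(run(), run())


class TestRESPA:
    def test_degenerate_split_matches_baoab_bitwise(self):
        split = ForceSplit(fast=_oscillator(), slow=_zero_provider)
        a, b = _single_atom(0.8), _single_atom(0.8)
        rng_a, rng_b = make_rng(5), make_rng(5)
        fa = slow = fast = None
        for _ in range(50):
            fa = baoab_step(a, _oscillator(), 0.5, 300.0, 0.02, rng_a,
                            forces=fa)
            slow, fast = respa_step(b, split, 0.5, 0.5, 300.0, 0.02, rng_b,
                                    slow_forces=slow, fast_forces=fast)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_gamma_zero_full_fast_matches_verlet(self):
        split = ForceSplit(fast=_oscillator(), slow=_zero_provider)
        a, b = _single_atom(0.8), _single_atom(0.8)
        fa = slow = fast = None
        rng = make_rng(1)
        for _ in range(100):
            fa = velocity_verlet_step(a, _oscillator(), 0.5, forces=fa)
            slow, fast = respa_step(b, split, 0.5, 0.5, 300.0, 0.0, rng,
                                    slow_forces=slow, fast_forces=fast)
        assert abs(a.coordinates[0, 0] - b.coordinates[0, 0]) < 1e-12

    def test_respa1_degenerate_mid_matches_respa(self):
        # all non-bonded force on the mid level, zero slow: RESPA1 with
        # n_outer = 1 must reproduce two-level RESPA bitwise
        split2 = ForceSplit(fast=_oscillator(1.0), slow=_oscillator(0.3))
        split3 = ForceSplit(fast=_oscillator(1.0), mid=_oscillator(0.3),
                            slow=_zero_provider)
        a, b = _single_atom(0.6), _single_atom(0.6)
        rng_a, rng_b = make_rng(9), make_rng(9)
        sa = fa = None
        sb = mb = fb = None
        for _ in range(30):
            sa, fa = respa_step(a, split2, 0.25, 1.0, 300.0, 0.01, rng_a,
                                slow_forces=sa, fast_forces=fa)
            sb, mb, fb = respa1_step(b, split3, 0.25, 1.0, 1.0, 300.0, 0.01,
                                     rng_b, slow_forces=sb, mid_forces=mb,
                                     fast_forces=fb)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_force_split_completeness(self):
        from hybridmd.forcefield import (FFSettings, ForceField,
                                         bonded_energy_forces,
                                         short_range_nonbonded)
        from hybridmd.synthetic import generate_water_box

        system = generate_water_box(16, seed=2)
        st = FFSettings(vdw_cutoff=3.6, ewald_real_cutoff=3.6,
                        neighbor_skin=0.2)
        ff = ForceField(st)

        def total(sy):
            return ff.energy_forces(sy, reuse_mu=True)

        def fast(sy):
            return bonded_energy_forces(sy.coordinates, sy.parameters, sy.box)

        def mid(sy):
            return short_range_nonbonded(sy, st, switch_r=3.0)

        split = ForceSplit.from_total(total, fast, mid)
        full = total(system)
        pieces = (fast(system).forces + mid(system).forces
                  + split.slow(system).forces)
        assert np.abs(pieces - full.forces).max() < 1e-10


class TestThermostatBarostat:
    def test_bussi_fixed_point_long_tau(self):
        from hybridmd.synthetic import generate_water_box

        system = generate_water_box(8, seed=0)
        rng = np.random.default_rng(0)
        draw_maxwell_boltzmann(system, 300.0, rng)
        factor = bussi_rescale(system, instantaneous_temperature(system),
                               tau=1e9, dt=1.0, rng=make_rng(0))
        assert abs(factor - 1.0) < 1e-3

    def test_bussi_kinetic_energy_distribution(self):
        # a free gas under the Bussi thermostat samples the canonical
        # kinetic-energy (chi-squared) distribution
        from hybridmd.synthetic import generate_water_box

        system = generate_water_box(8, seed=1)
        rng_draw = np.random.default_rng(1)
        draw_maxwell_boltzmann(system, 300.0, rng_draw)
        rng = make_rng(2)
        n_dof = 3 * system.n_atoms - 3
        samples = []
        for i in range(20_000):
            bussi_rescale(system, 300.0, tau=2.0, dt=1.0, rng=rng)
            if i % 20 == 0:  # well beyond the coupling time
                ke = kinetic_energy(system.masses, system.velocities)
                samples.append(2 * ke / (KB * 300.0))
        stat = kstest(samples, "chi2", args=(n_dof,))
        assert stat.pvalue > 0.01

    def test_bussi_reproducible_under_seed(self):
        from hybridmd.synthetic import generate_water_box

        def run():
            system = generate_water_box(4, seed=0)
            draw_maxwell_boltzmann(system, 300.0, np.random.default_rng(0))
            rng = make_rng(11)
            return [bussi_rescale(system, 300.0, 20.0, 1.0, rng)
                    for _ in range(20)]
        assert run() == run()

    def test_berendsen_no_change_at_target(self):
        from hybridmd.synthetic import generate_water_box

        system = generate_water_box(4, seed=0)
        mu = berendsen_scale(system, pressure=1.0, p_target=1.0,
                             tau_p=1000.0, dt=25.0)
        assert mu == 1.0

    def test_berendsen_clamps_pathological_virial(self):
        from hybridmd.synthetic import generate_water_box

        system = generate_water_box(4, seed=0)
        with pytest.warns(UserWarning, match="clamped"):
            mu = berendsen_scale(system, pressure=-1e9, p_target=1.0,
                                 tau_p=10.0, dt=25.0)
        assert 0.9 <= mu <= 1.1

    def test_ideal_gas_pressure(self):
        # no interactions: P V = N kB T
        from hybridmd.dynamics import measure_pressure
        from hybridmd.constants import ATM_TO_KCAL_PER_A3

        system = AtomicSystem(species=["C"] * 50,
                              coordinates=np.random.default_rng(0).uniform(
                                  0, 20, (50, 3)),
                              box=PeriodicBox([20.0] * 3))
        draw_maxwell_boltzmann(system, 300.0, np.random.default_rng(1),
                               remove_com=False)
        p = measure_pressure(system, _zero_provider)
        ke = kinetic_energy(system.masses, system.velocities)
        expected = (2 * ke / 3.0) / system.box.volume / ATM_TO_KCAL_PER_A3
        assert abs(p - expected) / expected < 1e-8


class TestRunDriver:
    def test_zero_steps_initial_frame_only(self):
        system = _single_atom()
        cfg = IntegratorConfig(scheme="verlet", dt_inner=0.5, seed=0)
        result = run_md(system, _oscillator(), cfg, n_steps=0)
        assert len(result.frames) == 1

    def test_same_seed_bitwise_identical(self):
        def run():
            system = _single_atom(0.5)
            cfg = IntegratorConfig(scheme="baoab", dt_inner=0.5,
                                   friction=0.02, seed=3)
            return run_md(system, _oscillator(), cfg, n_steps=100,
                          stride=10).frames[-1]
        np.testing.assert_array_equal(run(), run())
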