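"""Integrators and ensemble controls.

The multi-timestep schemes follow the impulse (RESPA) construction with a
BAOAB Langevin core: slow forces kick at the outer timestep, the inner loop
propagates the fast (bonded) forces with BAOAB, and — in the three-level
RESPA1 variant — an intermediate level carries the switched short-range
non-bonded forces.  The ML/FF difference potential dV_ML rides on the
slowest level, which is the entire point of the hybrid splitting: its
forces are small and slowly varying, so the expensive ML gradient is
evaluated rarely.

All stochastic updates draw from a counter-based Philox generator seeded
from the run seed, so trajectories are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATM_TO_KCAL_PER_A3, INTERNAL_PER_KCAL, KB, kinetic_energy
from .system import AtomicSystem, EnergyReport, instantaneous_temperature


def _accel(forces: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """kcal/mol/A forces to A/fs^2 accelerations."""
    return forces * INTERNAL_PER_KCAL / masses[:, None]


def make_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass
class IntegratorConfig:
    scheme: str = "baoab"            # verlet | baoab | respa | respa1
    dt_inner: float = 0.25           # fs
    dt_mid: float | None = None      # fs, respa1 only
    dt_outer: float | None = None    # fs, respa/respa1
    temperature: float = 300.0       # K
    friction: float = 0.01           # fs^-1
    seed: int = 0
    hmr_factor: float = 1.0
    tau_t: float = 100.0             # fs, Bussi
    pressure: float | None = None    # atm; None = no barostat
    tau_p: float = 1000.0            # fs
    barostat_stride: int = 25

    def __post_init__(self):
        if self.scheme in ("respa", "respa1"):
            if self.dt_outer is None:
                raise ValueError("RESPA schemes need dt_outer")
            if self.scheme == "respa1":
                if self.dt_mid is None:
                    raise ValueError("RESPA1 needs dt_mid")
                if abs(self.dt_mid / self.dt_inner
                       - round(self.dt_mid / self.dt_inner)) > 1e-9:
                    raise ValueError("dt_mid must be an integer multiple of dt_inner")
                if abs(self.dt_outer / self.dt_mid
                       - round(self.dt_outer / self.dt_mid)) > 1e-9:
                    raise ValueError("dt_outer must be an integer multiple of dt_mid")
            else:
                if abs(self.dt_outer / self.dt_inner
                       - round(self.dt_outer / self.dt_inner)) > 1e-9:
                    raise ValueError("dt_outer must be an integer multiple of dt_inner")


@dataclass
class ForceSplit:
    """Fast/mid/slow force providers; each maps a system to an EnergyReport.

    ``mid`` is None for two-level RESPA.  The completeness contract —
    fast + mid + slow equals the full force — is the caller's to honor;
    `from_total` builds the slow level by subtraction so it holds by
    construction.
    """

    fast: callable
    slow: callable
    mid: callable | None = None

    @classmethod
    def from_total(cls, total: callable, fast: callable,
                   mid: callable | None = None) -> "ForceSplit":
        if mid is None:
            def slow(system):
                rep_t = total(system)
                rep_f = fast(system)
                return EnergyReport(
                    components={"slow": rep_t.total - rep_f.total},
                    forces=rep_t.forces - rep_f.forces)
            return cls(fast=fast, slow=slow)

        def slow(system):
            rep_t = total(system)
            rep_f = fast(system)
            rep_m = mid(system)
            return EnergyReport(
                components={"slow": rep_t.total - rep_f.total - rep_m.total},
                forces=rep_t.forces - rep_f.forces - rep_m.forces)
        return cls(fast=fast, slow=slow, mid=mid)


# ---------------------------------------------------------------------------
# elementary steps


def velocity_verlet_step(system: AtomicSystem, provider, dt: float,
                         forces: np.ndarray | None = None) -> np.ndarray:
    """One kick-drift-kick step in place; returns the new forces."""
    if forces is None:
        forces = provider(system).forces
    _assert_finite(forces)
    system.velocities += 0.5 * dt * _accel(forces, system.masses)
    system.coordinates += dt * system.velocities
    forces = provider(system).forces
    _assert_finite(forces)
    system.velocities += 0.5 * dt * _accel(forces, system.masses)
    return forces


def _ou_update(system: AtomicSystem, dt: float, temperature: float,
               gamma: float, rng: np.random.Generator) -> None:
    """Exact Ornstein-Uhlenbeck velocity update (the O in BAOAB)."""
    if gamma == 0.0:
        return
    c1 = np.exp(-gamma * dt)
    sigma = np.sqrt(KB * temperature * INTERNAL_PER_KCAL / system.masses)
    noise = rng.standard_normal((system.n_atoms, 3))
    system.velocities *= c1
    system.velocities += np.sqrt(1.0 - c1 * c1) * sigma[:, None] * noise


def baoab_step(system: AtomicSystem, provider, dt: float, temperature: float,
               gamma: float, rng: np.random.Generator,
               forces: np.ndarray | None = None) -> np.ndarray:
    """One BAOAB Langevin step; gamma = 0 reduces exactly to Verlet."""
    if forces is None:
        forces = provider(system).forces
    _assert_finite(forces)
    system.velocities += 0.5 * dt * _accel(forces, system.masses)
    system.coordinates += 0.5 * dt * system.velocities
    _ou_update(system, dt, temperature, gamma, rng)
    system.coordinates += 0.5 * dt * system.velocities
    forces = provider(system).forces
    _assert_finite(forces)
    system.velocities += 0.5 * dt * _accel(forces, system.masses)
    return forces


def respa_step(system: AtomicSystem, split: ForceSplit, dt_inner: float,
               dt_outer: float, temperature: float, gamma: float,
               rng: np.random.Generator,
               slow_forces: np.ndarray | None = None,
               fast_forces: np.ndarray | None = None):
    """One outer BAOAB-RESPA step: slow impulse, n inner BAOAB substeps,
    slow impulse.  Slow forces (non-bonded + dV_ML) are evaluated once per
    outer step; the O-step lives at the inner level."""
    n = int(round(dt_outer / dt_inner))
    if slow_forces is None:
        slow_forces = split.slow(system).forces
    system.velocities += 0.5 * dt_outer * _accel(slow_forces, system.masses)
    for _ in range(n):
        fast_forces = baoab_step(system, split.fast, dt_inner, temperature,
                                 gamma, rng, forces=fast_forces)
    slow_forces = split.slow(system).forces
    _assert_finite(slow_forces)
    system.velocities += 0.5 * dt_outer * _accel(slow_forces, system.masses)
    return slow_forces, fast_forces


def respa1_step(system: AtomicSystem, split: ForceSplit, dt_inner: float,
                dt_mid: float, dt_outer: float, temperature: float,
                gamma: float, rng: np.random.Generator,
                slow_forces: np.ndarray | None = None,
                mid_forces: np.ndarray | None = None,
                fast_forces: np.ndarray | None = None):
    """One outer RESPA1 step: three nested impulse levels
    (bonded / switched short-range non-bonded / long-range + dV_ML)."""
    if split.mid is None:
        raise ValueError("RESPA1 needs a mid-level force provider")
    n_mid = int(round(dt_outer / dt_mid))
    n_in = int(round(dt_mid / dt_inner))
    if slow_forces is None:
        slow_forces = split.slow(system).forces
    system.velocities += 0.5 * dt_outer * _accel(slow_forces, system.masses)
    for _ in range(n_mid):
        if mid_forces is None:
            mid_forces = split.mid(system).forces
        system.velocities += 0.5 * dt_mid * _accel(mid_forces, system.masses)
        for _ in range(n_in):
            fast_forces = baoab_step(system, split.fast, dt_inner,
                                     temperature, gamma, rng,
                                     forces=fast_forces)
        mid_forces = split.mid(system).forces
        _assert_finite(mid_forces)
        system.velocities += 0.5 * dt_mid * _accel(mid_forces, system.masses)
    slow_forces = split.slow(system).forces
    _assert_finite(slow_forces)
    system.velocities += 0.5 * dt_outer * _accel(slow_forces, system.masses)
    return slow_forces, mid_forces, fast_forces


# ---------------------------------------------------------------------------
# thermostat / barostat


def bussi_rescale(system: AtomicSystem, temperature: float, tau: float,
                  dt: float, rng: np.random.Generator,
                  n_constraints: int = 3) -> float:
    """Stochastic velocity rescaling (canonical sampling through velocity
    rescaling); returns the applied scaling factor."""
    n_dof = 3 * system.n_atoms - n_constraints
    ke = kinetic_energy(system.masses, system.velocities)
    if ke <= 0:
        raise ValueError("kinetic energy must be positive")
    ke_target = 0.5 * n_dof * KB * temperature
    c = np.exp(-dt / tau)
    r1 = rng.standard_normal()
    s = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    factor2 = (c + (1.0 - c) * ke_target * (r1**2 + s) / (n_dof * ke)
               + 2.0 * r1 * np.sqrt(c * (1.0 - c) * ke_target / (n_dof * ke)))
    factor = np.sqrt(max(factor2, 0.0))
    system.velocities *= factor
    return float(factor)


def measure_pressure(system: AtomicSystem, provider, delta: float = 1e-4) -> float:
    """Instantaneous pressure (atm) from the kinetic term and a central
    finite difference of the potential energy under isotropic scaling.

    Numerical -dU/dV is exact for any potential the provider implements,
    which sidesteps hand-deriving the Ewald reciprocal virial.
    """
    from .system import PeriodicBox

    v0 = system.box.volume
    u_plus, u_minus = [], []
    for sgn in (+1.0, -1.0):
        scale = 1.0 + sgn * delta
        trial = system.copy()
        trial.coordinates = system.coordinates * scale
        trial.box = PeriodicBox(system.box.edge_lengths * scale)
        u = provider(trial).total
        (u_plus if sgn > 0 else u_minus).append(u)
    dv = v0 * ((1.0 + delta) ** 3 - (1.0 - delta) ** 3)
    du_dv = (u_plus[0] - u_minus[0]) / dv
    ke = kinetic_energy(system.masses, system.velocities)
    p_kcal = (2.0 * ke / 3.0 - du_dv * v0) / v0
    return p_kcal / ATM_TO_KCAL_PER_A3


def berendsen_scale(system: AtomicSystem, pressure: float, p_target: float,
                    tau_p: float, dt: float,
                    compressibility: float = 4.6e-5) -> float:
    """Berendsen weak-coupling barostat: isotropic box/coordinate scaling.

    ``compressibility`` in atm^-1.  The per-step factor is clamped to
    [0.9, 1.1] with a warning on pathological virials.
    """
    import warnings

    mu3 = 1.0 - compressibility * dt / tau_p * (p_target - pressure)
    mu = np.sign(mu3) * np.abs(mu3) ** (1.0 / 3.0)
    if not 0.9 <= mu <= 1.1:
        warnings.warn(f"berendsen scaling factor {mu:.3f} clamped to [0.9, 1.1]")
        mu = min(max(mu, 0.9), 1.1)
    from .system import PeriodicBox

    system.coordinates *= mu
    system.box = PeriodicBox(system.box.edge_lengths * mu)
    return float(mu)


def _assert_finite(forces: np.ndarray) -> None:
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force encountered; halting")


def minimize(system: AtomicSystem, provider, max_iter: int = 200,
             gtol: float = 1.0) -> float:
    """Relax the configuration with L-BFGS (in place); returns the final
    potential energy.  Used to drain the excess potential energy of
    generated lattice starts before thermostatted production runs."""
    from scipy.optimize import minimize as _scipy_min

    shape = system.coordinates.shape

    def fun(x):
        system.coordinates = x.reshape(shape)
        rep = provider(system)
        return rep.total, -rep.forces.ravel()

    res = _scipy_min(fun, system.coordinates.ravel(), jac=True,
                     method="L-BFGS-B",
                     options={"maxiter": max_iter, "gtol": gtol})
    system.coordinates = res.x.reshape(shape)
    return float(res.fun)


# ---------------------------------------------------------------------------
# run driver


@dataclass
class MDResult:
    frames: list
    energies: list
    temperatures: list
    summary: dict
    monitor_status: str = "ok"


def run_md(system: AtomicSystem, provider, config: IntegratorConfig,
           n_steps: int, stride: int = 10, split: ForceSplit | None = None,
           monitor=None, strict_monitor: bool = False,
           report_energy: bool = True) -> MDResult:
    """Propagate ``n_steps`` outer steps and collect frames/statistics.

    ``provider`` evaluates the full potential (used for Verlet/BAOAB and
    for reporting); RESPA schemes take their forces from ``split``.
    ``monitor``, if given, is called with the list of recorded energies and
    may return a status string; 'halt-recommended' plus strict mode stops
    the run.
    """
    rng = make_rng(config.seed)
    frames = [system.coordinates.copy()]
    energies, temps = [], []
    slow = mid = fast = full = None
    for step in range(n_steps):
        if config.scheme == "verlet":
            full = velocity_verlet_step(system, provider, config.dt_inner,
                                        forces=full)
        elif config.scheme == "baoab":
            full = baoab_step(system, provider, config.dt_inner,
                              config.temperature, config.friction, rng,
                              forces=full)
        elif config.scheme == "respa":
            slow, fast = respa_step(system, split, config.dt_inner,
                                    config.dt_outer, config.temperature,
                                    config.friction, rng,
                                    slow_forces=slow, fast_forces=fast)
        elif config.scheme == "respa1":
            slow, mid, fast = respa1_step(system, split, config.dt_inner,
                                          config.dt_mid, config.dt_outer,
                                          config.temperature, config.friction,
                                          rng, slow_forces=slow,
                                          mid_forces=mid, fast_forces=fast)
        else:
            raise ValueError(f"unknown scheme {config.scheme!r}")

        if config.pressure is not None and (step + 1) % config.barostat_stride == 0:
            p_now = measure_pressure(system, provider)
            berendsen_scale(system, p_now, config.pressure, config.tau_p,
                            config.barostat_stride * (config.dt_outer or config.dt_inner))
            slow = mid = fast = full = None  # box changed; stale forces

        if (step + 1) % stride == 0:
            frames.append(system.coordinates.copy())
            if report_energy:
                energies.append(provider(system).total)
            n_con = 3 if system.n_atoms > 1 else 0
            temps.append(instantaneous_temperature(system, n_constraints=n_con))
            if monitor is not None:
                status = monitor(energies)
                if status == "halt-recommended" and strict_monitor:
                    summary = _summary(energies, temps, config, halted=True)
                    return MDResult(frames, energies, temps, summary,
                                    monitor_status=status)
    summary = _summary(energies, temps, config, halted=False)
    return MDResult(frames, energies, temps, summary)


def _summary(energies, temps, config, halted):
    return {
        "n_samples": len(energies),
        "mean_energy": float(np.mean(energies)) if energies else None,
        "mean_temperature": float(np.mean(temps)) if temps else None,
        "scheme": config.scheme,
        "seed": config.seed,
        "halted": halted,
    }
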