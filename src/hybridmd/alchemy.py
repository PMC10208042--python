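"""Alchemical decoupling and Bennett-acceptance-ratio free energies.

The solute is decoupled from its environment along a lambda schedule that
first annihilates its permanent electrostatics and polarizabilities
(lam_ele 1 -> 0 at full vdW) and then scales away the solute-environment
van der Waals interactions through a softcore (lam_vdw 1 -> 0).  Adjacent
windows are bridged by BAR on forward/backward potential-energy
differences; errors come from Bennett's asymptotic formula and from a
seeded bootstrap.

When the hybrid (ML) surface is too expensive or has desynchronized from
the force field, the reweighting fallback runs the windows on the pure FF
surface and corrects the end states by one-sided exponential reweighting
onto the hybrid surface — no ML gradients are ever needed there, only
energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import KB
from .dynamics import IntegratorConfig, baoab_step, make_rng
from .hybrid import HybridPotential
from .system import AtomicSystem


# ---------------------------------------------------------------------------
# schedule


@dataclass(frozen=True)
class LambdaWindow:
    lam_ele: float
    lam_vdw: float


@dataclass
class LambdaSchedule:
    """Ordered decoupling windows from (1,1) to (0,0)."""

    windows: list[LambdaWindow]

    def __post_init__(self):
        if len(self.windows) < 2:
            raise ValueError("need at least two windows")
        w0, w1 = self.windows[0], self.windows[-1]
        if (w0.lam_ele, w0.lam_vdw) != (1.0, 1.0):
            raise ValueError("schedule must start fully coupled at (1, 1)")
        if (w1.lam_ele, w1.lam_vdw) != (0.0, 0.0):
            raise ValueError("schedule must end fully decoupled at (0, 0)")
        for a, b in zip(self.windows, self.windows[1:]):
            if b.lam_ele > a.lam_ele + 1e-12 or b.lam_vdw > a.lam_vdw + 1e-12:
                raise ValueError("lambdas must decrease monotonically")

    def __len__(self):
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def build_schedule(n_windows: int = 21, split_fraction: float = None) -> LambdaSchedule:
    """Default protocol: electrostatics off first, then softcore vdW.

    With 21 windows: 11 electrostatic windows (lam_ele 1 -> 0 at
    lam_vdw = 1) and 11 vdW windows (lam_vdw 1 -> 0 at lam_ele = 0)
    sharing the (0, 1) midpoint; spacing uniform per segment.
    """
    if n_windows < 2:
        raise ValueError("need at least two windows")
    if n_windows == 2:
        return LambdaSchedule([LambdaWindow(1.0, 1.0), LambdaWindow(0.0, 0.0)])
    n_ele = (n_windows + 1) // 2
    n_vdw = n_windows + 1 - n_ele
    ele = np.linspace(1.0, 0.0, n_ele)
    vdw = np.linspace(1.0, 0.0, n_vdw)
    windows = [LambdaWindow(float(l), 1.0) for l in ele]
    windows += [LambdaWindow(0.0, float(l)) for l in vdw[1:]]
    return LambdaSchedule(windows)


def scaled_hybrid_provider(hp: HybridPotential, lam_ele: float, lam_vdw: float):
    """Force provider evaluating the hybrid potential at fixed lambdas."""
    if not (0.0 <= lam_ele <= 1.0 and 0.0 <= lam_vdw <= 1.0):
        raise ValueError("lambdas must lie in [0, 1]")

    def provider(system: AtomicSystem):
        return hp.energy_forces(system, lam_ele=lam_ele, lam_vdw=lam_vdw)

    return provider


# ---------------------------------------------------------------------------
# estimators


@dataclass
class WorkSamples:
    """Forward/backward energy differences between two adjacent windows."""

    forward: np.ndarray      # U_next - U_this, on this-window samples
    backward: np.ndarray     # U_this - U_next, on next-window samples
    temperature: float = 300.0

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if not (np.all(np.isfinite(self.forward))
                and np.all(np.isfinite(self.backward))):
            raise ValueError("work samples must be finite")


@dataclass
class FreeEnergyResult:
    """Chained per-window free energies (kcal/mol) with error estimates."""

    window_dg: list[float]
    window_err: list[float]
    bootstrap_err: float | None = None
    sample_counts: list[tuple[int, int]] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.window_dg))

    @property
    def total_err(self) -> float:
        return float(np.sqrt(np.sum(np.square(self.window_err))))


def _fermi(x):
    # overflow-safe logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_estimate(samples: WorkSamples) -> tuple[float, float]:
    """Bennett acceptance ratio: dG and its asymptotic standard error.

    Solves the self-consistent equation by bracketed root finding to
    1e-8 kcal/mol.  Degenerate overlap yields an infinite error estimate
    rather than a silent number.
    """
    wf, wr = samples.forward, samples.backward
    if wf.size < 1 or wr.size < 1:
        raise ValueError("BAR needs samples in both directions")
    beta = 1.0 / (KB * samples.temperature)
    m = np.log(wf.size / wr.size)

    def implicit(dg):
        a = np.sum(_fermi(m + beta * (wf - dg)))
        b = np.sum(_fermi(-m + beta * (wr + dg)))
        return a - b

    lo = min(float(np.min(wf)), float(-np.max(wr))) - 10.0 / beta
    hi = max(float(np.max(wf)), float(-np.min(wr))) + 10.0 / beta
    flo, fhi = implicit(lo), implicit(hi)
    grow = 0
    while flo * fhi > 0 and grow < 60:
        span = hi - lo
        lo -= span
        hi += span
        flo, fhi = implicit(lo), implicit(hi)
        grow += 1
    if flo * fhi > 0:
        # no overlap between the distributions
        return float(np.mean(wf)), float("inf")
    dg = brentq(implicit, lo, hi, xtol=1e-8)

    ff = _fermi(m + beta * (wf - dg))
    fr = _fermi(-m + beta * (wr + dg))
    with np.errstate(divide="ignore", invalid="ignore"):
        var = ((np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / wf.size
               + (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / wr.size)
    err = float(np.sqrt(var) / beta) if np.isfinite(var) and var >= 0 else float("inf")
    return float(dg), err


def bootstrap_error(samples: WorkSamples, n_boot: int = 200,
                    seed: int = 0) -> float:
    """Standard deviation of BAR over resampled forward/backward sets."""
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        f = rng.choice(samples.forward, size=samples.forward.size, replace=True)
        r = rng.choice(samples.backward, size=samples.backward.size, replace=True)
        estimates[b] = bar_estimate(
            WorkSamples(f, r, samples.temperature))[0]
    return float(np.std(estimates))


def one_sided_exponential(delta_u: np.ndarray, temperature: float):
    """Zwanzig free-energy perturbation with an effective-sample-size
    diagnostic; used only for surface-change terms in reweighting."""
    delta_u = np.asarray(delta_u, dtype=float)
    beta = 1.0 / (KB * temperature)
    x = -beta * delta_u
    xmax = float(np.max(x))
    logmean = xmax + np.log(np.mean(np.exp(x - xmax)))
    w = np.exp(x - xmax)
    ess = float(np.sum(w)) ** 2 / float(np.sum(w**2))
    return -logmean / beta, ess


def binding_dg(dg_complex: tuple[float, float],
               dg_solution: tuple[float, float]) -> tuple[float, float]:
    """Double decoupling: dG_bind = dG_decouple(solution) - dG_decouple(complex).

    Favorable binding comes out negative; errors combine in quadrature.
    """
    dg = dg_solution[0] - dg_complex[0]
    err = float(np.hypot(dg_complex[1], dg_solution[1]))
    return dg, err


# ---------------------------------------------------------------------------
# sampling drivers


def _sample_window(system, hp, lam_pair, md_config, n_steps, n_equil, stride,
                   rng, neighbor_lams, extra_energy_fn=None):
    """BAOAB sampling in one window; returns cross-energies per neighbor."""
    lam_ele, lam_vdw = lam_pair
    provider = scaled_hybrid_provider(hp, lam_ele, lam_vdw)
    forces = None
    cross = {k: [] for k in neighbor_lams}
    extra = []
    for step in range(n_equil + n_steps):
        forces = baoab_step(system, provider, md_config.dt_inner,
                            md_config.temperature, md_config.friction, rng,
                            forces=forces)
        if step >= n_equil and (step - n_equil + 1) % stride == 0:
            u_here = hp.ff.energy_forces(
                system, lam_ele=lam_ele, lam_vdw=lam_vdw,
                solute_mask=hp.solute_mask(system.n_atoms)).total
            for key, (le, lv) in neighbor_lams.items():
                u_there = hp.ff.energy_forces(
                    system, lam_ele=le, lam_vdw=lv,
                    solute_mask=hp.solute_mask(system.n_atoms)).total
                cross[key].append(u_there - u_here)
            if extra_energy_fn is not None:
                extra.append(extra_energy_fn(system))
    return cross, extra


def run_decoupling(system: AtomicSystem, hp: HybridPotential,
                   schedule: LambdaSchedule, md_config: IntegratorConfig,
                   n_steps_per_window: int = 200, n_equil: int = 50,
                   stride: int = 10, n_boot: int = 200,
                   extra_energy_fn=None) -> FreeEnergyResult:
    """Sequential decoupling run: sample each window, cross-evaluate the
    potential at the neighboring lambdas, chain BAR over adjacent pairs.

    Windows are visited in order, each starting from the previous
    window's final configuration after ``n_equil`` re-equilibration
    steps.  Only potential-energy differences of the lambda-dependent
    full-system FF term enter the work values (the ML and isolated-solute
    terms are lambda-independent and cancel between windows).
    """
    rng = make_rng(md_config.seed)
    work = system.copy()
    forward: list[list[float]] = []
    backward: list[list[float]] = []
    extras: list[list[float]] = []
    n_win = len(schedule)
    for w, win in enumerate(schedule):
        neighbors = {}
        if w + 1 < n_win:
            nxt = schedule.windows[w + 1]
            neighbors["fwd"] = (nxt.lam_ele, nxt.lam_vdw)
        if w > 0:
            prv = schedule.windows[w - 1]
            neighbors["bwd"] = (prv.lam_ele, prv.lam_vdw)
        cross, extra = _sample_window(
            work, hp, (win.lam_ele, win.lam_vdw), md_config,
            n_steps_per_window, n_equil, stride, rng, neighbors,
            extra_energy_fn)
        if "fwd" in cross:
            forward.append(cross["fwd"])
        if "bwd" in cross:
            backward.append(cross["bwd"])
        extras.append(extra)

    window_dg, window_err, counts = [], [], []
    boot_var = 0.0
    for w in range(n_win - 1):
        samples = WorkSamples(forward[w], backward[w],
                              temperature=md_config.temperature)
        dg, err = bar_estimate(samples)
        b = bootstrap_error(samples, n_boot=n_boot, seed=md_config.seed + w)
        window_dg.append(dg)
        window_err.append(err)
        boot_var += b * b
        counts.append((samples.forward.size, samples.backward.size))
    return FreeEnergyResult(
        window_dg=window_dg, window_err=window_err,
        bootstrap_err=float(np.sqrt(boot_var)),
        sample_counts=counts,
        diagnostics={
            "seed": md_config.seed,
            "stride": stride,
            "n_steps_per_window": n_steps_per_window,
            "n_equil": n_equil,
            "schedule": [(w.lam_ele, w.lam_vdw) for w in schedule],
            "extras": extras,
        },
    )


def reweight_bar(system: AtomicSystem, ff_hp: HybridPotential,
                 hyb_hp: HybridPotential, schedule: LambdaSchedule,
                 md_config: IntegratorConfig, n_steps_per_window: int = 200,
                 n_equil: int = 50, stride: int = 10,
                 min_ess: float = 10.0) -> FreeEnergyResult:
    """Free energy on the hybrid surface from FF-only trajectories.

    ``ff_hp`` must be the hybrid potential with the FF-mimic ML adapter
    (i.e. the pure force-field surface); ``hyb_hp`` the true hybrid.  The
    windows are sampled on the FF surface (no ML gradients), BAR is chained
    there, and each window's dG is corrected by one-sided exponential
    estimates of the FF -> hybrid surface change at its end states:

        dG_hyb(w) = dG_FF(w) - dG_surf(lam_w) + dG_surf(lam_w+1)

    The surface-change term is the lambda-independent dV_ML = V_ML - V_FF(P)
    evaluated on FF samples.  Windows with effective sample size below
    ``min_ess`` are flagged in the diagnostics.
    """
    def delta_v_ml(sys_now):
        return hyb_hp.delta_ml_energy_forces(sys_now).total

    ff_result = run_decoupling(system, ff_hp, schedule, md_config,
                               n_steps_per_window, n_equil, stride,
                               extra_energy_fn=delta_v_ml)
    extras = ff_result.diagnostics["extras"]
    t = md_config.temperature
    corr, esss = [], []
    for w in range(len(schedule)):
        dg_surf, ess = one_sided_exponential(np.asarray(extras[w]), t)
        corr.append(dg_surf)
        esss.append(ess)
    window_dg = [ff_result.window_dg[w] - corr[w] + corr[w + 1]
                 for w in range(len(schedule) - 1)]
    flagged = [w for w, e in enumerate(esss) if e < min_ess]
    return FreeEnergyResult(
        window_dg=window_dg,
        window_err=ff_result.window_err,
        bootstrap_err=ff_result.bootstrap_err,
        sample_counts=ff_result.sample_counts,
        diagnostics={
            "surface_corrections": corr,
            "effective_sample_sizes": esss,
            "low_overlap_windows": flagged,
            "ff_total": ff_result.total,
            **{k: v for k, v in ff_result.diagnostics.items() if k != "extras"},
        },
    )
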