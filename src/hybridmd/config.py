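"""Run configuration: YAML-backed, schema-validated, no silent defaults
for misspelled keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import IntegratorConfig
from .forcefield import FFSettings


@dataclass
class RunConfig:
    """Everything a reproducible run needs; unknown keys are rejected."""

    integrator: str = "baoab"
    dt_inner: float = 0.25
    dt_mid: float | None = None
    dt_outer: float | None = None
    temperature: float = 300.0
    pressure: float | None = None
    friction: float = 0.01
    tau_t: float = 100.0
    tau_p: float = 1000.0
    seed: int = 0
    hmr_factor: float = 1.0
    n_steps: int = 100
    stride: int = 10
    vdw_cutoff: float = 5.8
    ewald_real_cutoff: float = 5.8
    ewald_accuracy: float = 1e-7
    pol_tolerance: float = 1e-5
    neighbor_skin: float = 0.4
    n_windows: int = 21
    steps_per_window: int = 200
    equil_steps: int = 50
    output: str = "run_output"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(d)

    def integrator_config(self) -> IntegratorConfig:
        return IntegratorConfig(
            scheme=self.integrator, dt_inner=self.dt_inner,
            dt_mid=self.dt_mid, dt_outer=self.dt_outer,
            temperature=self.temperature, friction=self.friction,
            seed=self.seed, hmr_factor=self.hmr_factor, tau_t=self.tau_t,
            pressure=self.pressure, tau_p=self.tau_p,
        )

    def ff_settings(self) -> FFSettings:
        return FFSettings(
            vdw_cutoff=self.vdw_cutoff,
            ewald_real_cutoff=self.ewald_real_cutoff,
            ewald_accuracy=self.ewald_accuracy,
            pol_tolerance=self.pol_tolerance,
            neighbor_skin=self.neighbor_skin,
        )

    def to_dict(self) -> dict:
        return asdict(self)
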