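"""High-dimensional neural-network potential on top of AEV descriptors.

The total energy is a sum of atomic contributions: each atom's AEV is fed
through the feed-forward network of its element, plus a per-element energy
shift.  Forces follow by the chain rule through the analytic AEV Jacobian.
An ensemble averages member energies and forces and reports the member
spread.  Models serialize losslessly to JSON or YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .descriptors import AEVSpec, assemble_aev, aev_jacobian
from .system import EnergyReport

SCHEMA_VERSION = 1

_ACTIVATIONS = {}


def _register(name):
    def deco(fn):
        _ACTIVATIONS[name] = fn
        return fn
    return deco


@_register("celu")
def _celu(x, alpha=0.1):
    """Smooth CELU: C^1 everywhere, so forces are continuous."""
    val = np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0) / alpha))
    grad = np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0) / alpha))
    return val, grad


@_register("tanh")
def _tanh(x):
    t = np.tanh(x)
    return t, 1.0 - t**2


@_register("gaussian")
def _gaussian(x):
    g = np.exp(-(x**2))
    return x * 0 + (1.0 - g), 2.0 * x * g  # integral-of-gaussian style softplus-like


@dataclass
class SpeciesNetwork:
    """Fully connected network for one element; linear output layer."""

    weights: list[np.ndarray]     # layer l: (n_out, n_in)
    biases: list[np.ndarray]      # (n_out,)
    activation: str = "celu"

    def __post_init__(self):
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        if len(self.weights) != len(self.biases):
            raise ValueError("weights/biases length mismatch")
        for (w, b) in zip(self.weights, self.biases):
            if w.shape[0] != b.shape[0]:
                raise ValueError("layer dimension mismatch")
        for w1, w2 in zip(self.weights, self.weights[1:]):
            if w2.shape[1] != w1.shape[0]:
                raise ValueError("layers do not chain")
        if self.weights[-1].shape[0] != 1:
            raise ValueError("output layer must be scalar")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[1]

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Scalar output and its gradient w.r.t. the input vector."""
        return self.forward(x), self._grad(x)

    def _grad(self, x: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation]
        h = np.asarray(x, dtype=float)
        local = []
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = w @ h + b
            if l < len(self.weights) - 1:
                h, g = act(z)
                local.append((w, g))
        delta = self.weights[-1][0].copy()
        for w, g in reversed(local):
            delta = w.T @ (delta * g)
        return delta

    def forward(self, x: np.ndarray) -> float:
        act = _ACTIVATIONS[self.activation]
        h = np.asarray(x, dtype=float)
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = w @ h + b
            h = act(z)[0] if l < len(self.weights) - 1 else z
        return float(h[0])


@dataclass
class MLPModel:
    """Descriptor spec + one network per element + per-element energy shifts."""

    aev_spec: AEVSpec
    networks: dict[str, SpeciesNetwork]
    shifts: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for el in self.aev_spec.elements:
            if el not in self.networks:
                raise ValueError(f"element {el} has no network")
            if self.networks[el].input_dim != self.aev_spec.aev_length:
                raise ValueError(
                    f"network for {el} expects input {self.networks[el].input_dim}, "
                    f"AEV length is {self.aev_spec.aev_length}"
                )
            self.shifts.setdefault(el, 0.0)

    @property
    def elements(self) -> tuple[str, ...]:
        return self.aev_spec.elements

    def atomic_energy(self, aev: np.ndarray, species: str) -> float:
        """Energy contribution of a single atom from its AEV (kcal/mol)."""
        if species not in self.networks:
            raise ValueError(f"no network for element {species!r}")
        return self.networks[species].forward(aev) + self.shifts[species]

    def energy_forces(self, species: list[str], coords: np.ndarray) -> EnergyReport:
        """Total ML energy and forces of an isolated cluster (the solute)."""
        coords = np.asarray(coords, dtype=float)
        for s in set(species):
            if s not in self.networks:
                raise ValueError(f"unsupported element {s!r} for the ML potential")
        n = coords.shape[0]
        energy = 0.0
        forces = np.zeros((n, 3))
        for i in range(n):
            aev = assemble_aev(coords, species, i, self.aev_spec)
            e = self.networks[species[i]].forward(aev) + self.shifts[species[i]]
            g = self.networks[species[i]]._grad(aev)
            jac = aev_jacobian(coords, species, i, self.aev_spec)
            forces -= np.einsum("m,mnx->nx", g, jac)
            energy += e
        return EnergyReport(components={"ml": energy}, forces=forces)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "elements": list(self.elements),
            "aev_spec": self.aev_spec.to_dict(),
            "networks": {
                el: {
                    "layers": [list(w.shape) for w in net.weights],
                    "weights": [w.tolist() for w in net.weights],
                    "biases": [b.tolist() for b in net.biases],
                    "activation": net.activation,
                }
                for el, net in self.networks.items()
            },
            "shifts": {el: float(v) for el, v in self.shifts.items()},
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {version!r} not supported "
                f"(expected {SCHEMA_VERSION})"
            )
        networks = {
            el: SpeciesNetwork(
                weights=[np.array(w) for w in nd["weights"]],
                biases=[np.array(b) for b in nd["biases"]],
                activation=nd.get("activation", "celu"),
            )
            for el, nd in d["networks"].items()
        }
        return cls(
            aev_spec=AEVSpec.from_dict(d["aev_spec"]),
            networks=networks,
            shifts={el: float(v) for el, v in d.get("shifts", {}).items()},
            metadata=d.get("metadata", {}),
        )


def save_model(model: MLPModel, path, fmt: str | None = None) -> None:
    """Serialize a model to JSON or YAML (chosen by extension if fmt is None)."""
    path = Path(path)
    if fmt is None:
        fmt = "yaml" if path.suffix.lower() in (".yml", ".yaml") else "json"
    d = model.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(d))
    elif fmt == "yaml":
        path.write_text(yaml.safe_dump(d, default_flow_style=None))
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def load_model(path) -> MLPModel:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    if not isinstance(d, dict):
        raise ValueError("model file does not contain a mapping")
    return MLPModel.from_dict(d)


@dataclass
class MLPEnsemble:
    """Arithmetic-mean ensemble of models sharing one descriptor spec."""

    members: list[MLPModel]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        ref = self.members[0].elements
        for m in self.members[1:]:
            if m.elements != ref:
                raise ValueError("ensemble members must share the element order")

    @property
    def aev_spec(self) -> AEVSpec:
        return self.members[0].aev_spec

    @property
    def elements(self):
        return self.members[0].elements

    def energy_forces(self, species, coords) -> EnergyReport:
        reports = [m.energy_forces(species, coords) for m in self.members]
        mean_e = float(np.mean([r.total for r in reports]))
        mean_f = np.mean([r.forces for r in reports], axis=0)
        return EnergyReport(components={"ml": mean_e}, forces=mean_f)

    def predict_with_spread(self, species, coords) -> tuple[EnergyReport, float]:
        """Mean prediction plus the population std dev of member energies."""
        reports = [m.energy_forces(species, coords) for m in self.members]
        energies = np.array([r.total for r in reports])
        mean_f = np.mean([r.forces for r in reports], axis=0)
        rep = EnergyReport(components={"ml": float(energies.mean())}, forces=mean_f)
        return rep, float(energies.std())
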