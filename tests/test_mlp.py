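import numpy as np
import pytest

from conftest import random_cluster
from hybridmd.descriptors import AEVSpec
from hybridmd.mlp import (MLPEnsemble, MLPModel, SpeciesNetwork, load_model,
                          save_model)
from hybridmd.synthetic import generate_random_ensemble, generate_random_mlp


@pytest.fixture(scope="module")
def spec():
    return AEVSpec(elements=("H", "C", "O"))


def _zero_network(dim, shift_layers=(8,)):
    sizes = [dim, *shift_layers, 1]
    ws = [np.zeros((b, a)) for a, b in zip(sizes[:-1], sizes[1:])]
    bs = [np.zeros(b) for b in sizes[1:]]
    return SpeciesNetwork(ws, bs)


class TestAtomicEnergy:
    def test_zero_network_returns_shift(self, spec):
        model = MLPModel(spec, {e: _zero_network(spec.aev_length)
                                for e in spec.elements},
                         shifts={"H": -0.5, "C": -38.0, "O": -75.1})
        aev = np.random.default_rng(0).uniform(0, 1, spec.aev_length)
        assert model.atomic_energy(aev, "C") == -38.0

    def test_hand_propagated_two_layer_net(self):
        # tiny 2-input network evaluated by hand: E = w2 . celu(W1 x + b1) + b2
        spec = AEVSpec(elements=("H",), radial_shifts=np.array([1.0]),
                       angular_shifts=np.array([1.0]),
                       angular_thetas=np.array([1.0]),
                       angular_eta=np.array([8.0]),
                       angular_zeta=np.array([32.0]))
        assert spec.aev_length == 2
        w1 = np.array([[1.0, -2.0], [0.5, 0.25]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[2.0, -1.0]])
        b2 = np.array([0.3])
        net = SpeciesNetwork([w1, w2], [b1, b2], activation="celu")
        x = np.array([0.4, 0.7])
        z = w1 @ x + b1
        alpha = 0.1
        h = np.where(z > 0, z, alpha * np.expm1(z / alpha))
        expected = (w2 @ h + b2).item()
        model = MLPModel(spec, {"H": net})
        assert abs(model.atomic_energy(x, "H") - expected) < 1e-14

    def test_deterministic(self, spec):
        model = generate_random_mlp(spec.elements, seed=1, aev_spec=spec)
        aev = np.random.default_rng(2).uniform(0, 1, spec.aev_length)
        assert model.atomic_energy(aev, "O") == model.atomic_energy(aev, "O")

    def test_unknown_species_rejected(self, spec):
        model = generate_random_mlp(spec.elements, seed=1, aev_spec=spec)
        with pytest.raises(ValueError, match="network"):
            model.atomic_energy(np.zeros(spec.aev_length), "Cl")


class TestEnergyForces:
    def test_force_finite_difference(self, spec):
        rng = np.random.default_rng(4)
        model = generate_random_mlp(spec.elements, seed=4, aev_spec=spec,
                                    scale=0.3)
        h = 1e-5
        for _ in range(5):
            coords, species = random_cluster(rng, 6)
            rep = model.energy_forces(species, coords)
            fmax = max(np.abs(rep.forces).max(), 1e-3)
            for a in range(6):
                for x in range(3):
                    cp = coords.copy(); cp[a, x] += h
                    cm = coords.copy(); cm[a, x] -= h
                    fd = -(model.energy_forces(species, cp).total
                           - model.energy_forces(species, cm).total) / (2 * h)
                    assert abs(fd - rep.forces[a, x]) / fmax < 1e-6

    def test_locality_fragments_beyond_cutoff(self, spec):
        rng = np.random.default_rng(5)
        model = generate_random_mlp(spec.elements, seed=5, aev_spec=spec)
        c1, s1 = random_cluster(rng, 4)
        c2, s2 = random_cluster(rng, 3)
        c2 = c2 + np.array([50.0, 0.0, 0.0])  # far beyond R_c
        e1 = model.energy_forces(s1, c1).total
        e2 = model.energy_forces(s2, c2).total
        both = model.energy_forces(s1 + s2, np.vstack([c1, c2])).total
        assert abs(both - (e1 + e2)) < 1e-10

    def test_extensivity_duplicated_solute(self, spec):
        rng = np.random.default_rng(6)
        model = generate_random_mlp(spec.elements, seed=6, aev_spec=spec)
        coords, species = random_cluster(rng, 5)
        single = model.energy_forces(species, coords).total
        double = model.energy_forces(
            species * 2, np.vstack([coords, coords + 100.0])).total
        assert abs(double - 2 * single) < 1e-10

    def test_permutation_invariance(self, spec):
        rng = np.random.default_rng(7)
        model = generate_random_mlp(spec.elements, seed=7, aev_spec=spec)
        coords, _ = random_cluster(rng, 4)
        species = ["H", "H", "C", "O"]
        ref = model.energy_forces(species, coords).total
        perm = [1, 0, 2, 3]
        new = model.energy_forces([species[p] for p in perm],
                                  coords[perm]).total
        assert new == ref

    def test_net_force_and_torque_vanish(self, spec):
        rng = np.random.default_rng(8)
        model = generate_random_mlp(spec.elements, seed=8, aev_spec=spec,
                                    scale=0.3)
        coords, species = random_cluster(rng, 7)
        rep = model.energy_forces(species, coords)
        assert np.abs(rep.forces.sum(axis=0)).max() < 1e-8
        torque = np.cross(coords - coords.mean(axis=0), rep.forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-6


class TestSerialization:
    def test_json_roundtrip_bitwise(self, spec, tmp_path):
        rng = np.random.default_rng(9)
        model = generate_random_mlp(spec.elements, seed=9, aev_spec=spec)
        coords, species = random_cluster(rng, 5)
        ref = model.energy_forces(species, coords).total
        save_model(model, tmp_path / "m.json")
        again = load_model(tmp_path / "m.json").energy_forces(species, coords).total
        assert again == ref

    def test_json_yaml_json_chain(self, spec, tmp_path):
        rng = np.random.default_rng(10)
        model = generate_random_mlp(spec.elements, seed=10, aev_spec=spec)
        coords, species = random_cluster(rng, 4)
        ref = model.energy_forces(species, coords).total
        save_model(model, tmp_path / "m.json")
        save_model(load_model(tmp_path / "m.json"), tmp_path / "m.yaml")
        save_model(load_model(tmp_path / "m.yaml"), tmp_path / "m2.json")
        final = load_model(tmp_path / "m2.json")
        assert final.energy_forces(species, coords).total == ref

    def test_truncated_file_rejected(self, spec, tmp_path):
        model = generate_random_mlp(spec.elements, seed=11, aev_spec=spec)
        save_model(model, tmp_path / "m.json")
        text = (tmp_path / "m.json").read_text()
        (tmp_path / "bad.json").write_text(text[:len(text) // 2])
        with pytest.raises(Exception):
            load_model(tmp_path / "bad.json")

    def test_schema_version_mismatch(self, spec, tmp_path):
        import json
        model = generate_random_mlp(spec.elements, seed=12, aev_spec=spec)
        d = model.to_dict()
        d["schema_version"] = 99
        (tmp_path / "v.json").write_text(json.dumps(d))
        with pytest.raises(ValueError, match="version"):
            load_model(tmp_path / "v.json")


class TestEnsemble:
    def test_single_member_identity(self, spec):
        rng = np.random.default_rng(13)
        model = generate_random_mlp(spec.elements, seed=13, aev_spec=spec)
        ens = MLPEnsemble([model])
        coords, species = random_cluster(rng, 4)
        rep, spread = ens.predict_with_spread(species, coords)
        assert rep.total == model.energy_forces(species, coords).total
        assert spread == 0.0

    def test_two_member_mean_and_spread(self, spec):
        base = generate_random_mlp(spec.elements, seed=14, aev_spec=spec)
        shifted = MLPModel.from_dict(base.to_dict())
        shifted.shifts = {e: s + 2.0 for e, s in base.shifts.items()}
        ens = MLPEnsemble([base, shifted])
        rng = np.random.default_rng(15)
        coords, species = random_cluster(rng, 3)
        e0 = base.energy_forces(species, coords).total
        rep, spread = ens.predict_with_spread(species, coords)
        n = len(species)
        assert abs(rep.total - (e0 + n)) < 1e-10     # mean of E, E + 2n
        assert abs(spread - n) < 1e-10

    def test_eight_member_mean_matches_direct_sum(self, spec):
        ens = generate_random_ensemble(spec.elements, n_members=8, seed=16,
                                       aev_spec=spec)
        rng = np.random.default_rng(17)
        coords, species = random_cluster(rng, 4)
        rep = ens.energy_forces(species, coords)
        direct = np.mean([m.energy_forces(species, coords).total
                          for m in ens.members])
        assert abs(rep.total - direct) < 1e-12
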