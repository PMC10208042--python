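import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ff_settings():
    """Cutoffs sized for the small periodic test boxes."""
    from hybridmd.forcefield import FFSettings

    return FFSettings(vdw_cutoff=4.2, ewald_real_cutoff=4.2,
                      ewald_accuracy=1e-7, pol_tolerance=1e-6,
                      neighbor_skin=0.3)


@pytest.fixture(scope="session")
def water64_settings():
    """Cutoffs for the 64-water box (edge ~12.4 A, half box 6.2 A)."""
    from hybridmd.forcefield import FFSettings

    return FFSettings(vdw_cutoff=5.8, ewald_real_cutoff=5.8,
                      ewald_accuracy=1e-7, pol_tolerance=1e-6,
                      neighbor_skin=0.4)


@pytest.fixture(scope="session")
def solvated_ring():
    """Benzene-like ring in 20 toy waters; solute occupies indices 0..11."""
    from hybridmd.synthetic import generate_toy_solute, solvate
    from hybridmd.system import partition_system

    solute = generate_toy_solute("ring6", seed=0)
    system = solvate(solute, 20, seed=0)
    partition = partition_system(system, range(solute.n_atoms))
    return system, partition


def random_cluster(rng, n, elements=("H", "C", "O"), scale=1.5):
    """Random small cluster with no overlapping atoms."""
    while True:
        coords = rng.normal(scale=scale, size=(n, 3))
        iu, ju = np.triu_indices(n, 1)
        if n < 2 or np.linalg.norm(coords[iu] - coords[ju], axis=1).min() > 0.7:
            break
    species = [elements[i] for i in rng.integers(0, len(elements), size=n)]
    return coords, species
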