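import numpy as np
import pytest

from fespath.engine import MetaDParams, run_wtmetad
from fespath.landscape import fes_from_grid
from fespath.reweight import unbias_weights
from fespath.synthetic import (double_well_1d, planted_pose_ensemble,
                               reference_mechanism_surface, PlantedEnsembleSpec)
from fespath.consensus import cluster_ensemble


@pytest.fixture(scope="session")
def double_well_potential():
    return double_well_1d(5.0, 1.0)


@pytest.fixture(scope="session")
def double_well_run(double_well_potential):
    """Seeded well-tempered run on the 5 kcal/mol double well (1 ns)."""
    params = MetaDParams(seed=7)
    traj, hills = run_wtmetad(double_well_potential, params, 2_000_000, start=-1.0)
    return params, traj, hills


@pytest.fixture(scope="session")
def double_well_weights(double_well_run):
    _, traj, hills = double_well_run
    return unbias_weights(traj, hills, 298.0)


@pytest.fixture(scope="session")
def reference_surface():
    return reference_mechanism_surface()


@pytest.fixture(scope="session")
def reference_grid(reference_surface):
    return fes_from_grid(reference_surface, [(1.4, 5.2, 0.02), (0.8, 5.6, 0.02)])


@pytest.fixture(scope="session")
def planted_default():
    spec = PlantedEnsembleSpec(seed=1)
    ensemble, labels = planted_pose_ensemble(spec)
    return spec, ensemble, labels


@pytest.fixture(scope="session")
def planted_clustering(planted_default):
    _, ensemble, _ = planted_default
    return cluster_ensemble(ensemble)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
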