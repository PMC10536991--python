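import numpy as np
import pytest

from splinetb.geometry import Dataset, Geometry
from splinetb.synth import (make_targets, make_toy_paramset,
                            sample_geometries)


@pytest.fixture(scope="session")
def toy_params():
    """Full synthetic ground truth over H, C, N, O (built once)."""
    return make_toy_paramset()


@pytest.fixture(scope="session")
def toy_params_ho():
    """Cheaper two-element (H, O) ground truth for per-operation tests."""
    return make_toy_paramset(elements=(1, 8))


@pytest.fixture(scope="session")
def small_dataset(toy_params):
    """60 distorted configurations with toy-truth targets."""
    geoms = sample_geometries(
        templates=("H2", "H2O", "NH3", "CH4", "H2CO", "CH3OH"),
        n_per_template=10, seed=42)
    return make_targets(geoms, toy_params, seed=43)


@pytest.fixture()
def water():
    a = np.radians(104.5 / 2)
    return Geometry(np.array([8, 1, 1]),
                    np.array([[0.0, 0.0, 0.0],
                              [0.958 * np.sin(a), 0.0, 0.958 * np.cos(a)],
                              [-0.958 * np.sin(a), 0.0, 0.958 * np.cos(a)]]))


@pytest.fixture()
def h2():
    return Geometry(np.array([1, 1]),
                    np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.741]]))


def make_two_atom_dataset(distances, z=(1, 1)):
    ds = Dataset()
    for d in distances:
        ds.append(Geometry(np.array(z), np.array([[0.0, 0.0, 0.0],
                                                  [0.0, 0.0, float(d)]])))
    return ds
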