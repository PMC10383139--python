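import numpy as np
import pytest

from sorbscreen.trajectory import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_traj(coords, masses=None, box=(200.0, 200.0, 200.0), groups=None,
              dt=1.0, elements=None):
    """Minimal Trajectory builder for hand-made frames."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    return Trajectory(
        coords=coords,
        masses=np.ones(n_atoms) if masses is None else np.asarray(masses, float),
        elements=elements or ["C"] * n_atoms,
        groups=groups or {"all": np.arange(n_atoms)},
        box=np.asarray(box, float),
        times=np.arange(coords.shape[0]) * dt,
    )


@pytest.fixture
def make_trajectory():
    return make_traj
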