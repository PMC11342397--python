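import numpy as np
import pytest

from mabdyn.core_io import Topology, TrajectorySlice
from mabdyn.synthetic_data import ToyAntibodySpec, make_toy_antibody


def make_slice(top: Topology, coords: np.ndarray) -> TrajectorySlice:
    """Wrap (single- or multi-frame) coordinates as a TrajectorySlice."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    return TrajectorySlice(
        coordinates=coords,
        topology=top,
        atom_index=np.arange(top.n_atoms),
        frame_index=np.arange(coords.shape[0]),
    )


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-50, 50, size=3)


@pytest.fixture
def toy_system():
    spec = ToyAntibodySpec(theta1=70.0, theta2=70.0, phi1=30.0, phi2=150.0, n_frames=5)
    ann, traj = make_toy_antibody(spec)
    return spec, ann, traj


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
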