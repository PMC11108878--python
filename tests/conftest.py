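import numpy as np
import pytest

from corrshuttle import (
    PlantedNetworkParams,
    Site,
    SwitchingModelParams,
    Trajectory,
    TrajectoryEnsemble,
    simulate_switching_distances,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def coupled_sample():
    """Moderate-noise coupled switching sample used across modules."""
    params = SwitchingModelParams(n_frames=5000, seed=11)
    return simulate_switching_distances(params)


@pytest.fixture
def bead_chain_ensemble():
    """Small static bead chain with labeled residues (16 beads, zig-zag)."""
    n = 16
    rest = np.zeros((n, 3))
    rest[:, 0] = 0.4 * np.arange(n)
    rest[::2, 1] = 0.2  # break collinearity so superposition is well-posed
    coords = np.repeat(rest[None], 5, axis=0)
    topo = [Site("CA", i + 1, "ALA", "NET") for i in range(n)]
    return TrajectoryEnsemble(topo, [Trajectory(coords, frame_interval=0.1)])


def random_rotation(rng):
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
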