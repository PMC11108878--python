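"""Synthetic trajectories with known statistical ground truth.

Two generators drive the test bed:

* a two-state Markov-switching pair of distance traces with
  Ornstein–Uhlenbeck (OU) fluctuations, emulating the anticorrelated
  "shuttle" alternation of the two PscC cytochrome domains — when the two
  domains approach each other, the docked one backs away from the P840
  special pair, and vice versa;
* a bead-chain trajectory with a planted residue–residue correlation
  structure, the ground truth for correlation-network pathway recovery.

Defaults place the switching means at the distance regimes a realistic
system samples (Fe–Mg modes near 2.5 and 2.8 nm, Fe–Fe regimes within
2.7–3.2 nm) with sub-nm fluctuations.  Everything is reproducible from an
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .exceptions import AlignmentError, ParameterError
from .trajectory import DistanceSeries, Site, Trajectory, TrajectoryEnsemble

MIN_DISTANCE_NM = 0.1  # physical positivity clamp after noise addition


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchingModelParams:
    """Parameters of the two-state anticorrelated distance generator.

    ``mean_a`` / ``mean_b`` are (Fe–Fe, Fe–Mg) mean pairs in nm for the two
    hidden states: in state A the cytochrome domains are far apart and the
    docked one sits close to the special pair; state B is the reverse.
    ``sigma`` is the stationary OU fluctuation std (nm), ``theta`` the OU
    relaxation rate (1/ns), ``k_ab``/``k_ba`` the state transition rates
    (1/ns), ``dt`` the frame interval (ns).  ``coupled=False`` gives each
    series its own independent hidden chain (the null model).
    """

    mean_a: tuple[float, float] = (3.2, 2.5)
    mean_b: tuple[float, float] = (2.7, 2.8)
    sigma: float = 0.08
    theta: float = 1.0
    k_ab: float = 0.05
    k_ba: float = 0.05
    dt: float = 0.1
    n_frames: int = 20000
    seed: int = 0
    coupled: bool = True

    def __post_init__(self) -> None:
        if min(*self.mean_a, *self.mean_b) <= 0:
            raise ParameterError("state means must be positive distances (nm)")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        for nm, v in (("theta", self.theta), ("k_ab", self.k_ab), ("k_ba", self.k_ba), ("dt", self.dt)):
            if v <= 0:
                raise ParameterError(f"{nm} must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")

    def to_dict(self) -> dict:
        return {
            "mean_a": list(self.mean_a),
            "mean_b": list(self.mean_b),
            "sigma": self.sigma,
            "theta": self.theta,
            "k_ab": self.k_ab,
            "k_ba": self.k_ba,
            "dt": self.dt,
            "n_frames": self.n_frames,
            "seed": self.seed,
            "coupled": self.coupled,
        }


@dataclass(frozen=True)
class PlantedNetworkParams:
    """Parameters of the planted-correlation bead-ring generator.

    Beads sit on a ring so every bead contacts exactly two neighbours and the
    planted path (a contiguous arc) competes with the complement arc; pathway
    recovery is therefore a real inference, not a connectivity tautology.
    Displacements are zero-mean Gaussian with per-axis correlation
    ``on_path_correlation`` between consecutive planted beads,
    ``off_path_correlation`` between other contacting beads, and zero
    elsewhere.  Beads listed in ``mobile_residues`` (0-based) get their
    displacement std multiplied by ``mobile_scale`` — used to emulate the
    higher mobility of the distant cytochrome domain.
    """

    n_residues: int = 24
    planted_path: tuple[int, ...] = tuple(range(13))
    on_path_correlation: float = 0.9
    off_path_correlation: float = 0.1
    chain_geometry: float = 0.4
    n_frames: int = 20000
    displacement_std: float = 0.05
    mobile_scale: float = 1.0
    mobile_residues: tuple[int, ...] = ()
    subunit_split: int | None = None
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_residues
        if n < 3:
            raise ParameterError("need at least 3 residues for a ring layout")
        path = self.planted_path
        if len(path) < 2 or len(set(path)) != len(path):
            raise ParameterError("planted_path must list >= 2 distinct residues")
        if any(not (0 <= i < n) for i in path):
            raise ParameterError("planted_path indices out of range")
        for a, b in zip(path[:-1], path[1:]):
            if (b - a) % n != 1 and (a - b) % n != 1:
                raise ParameterError(
                    f"planted_path beads {a}->{b} are not ring neighbours "
                    "(must stay within the contact layout)"
                )
        if not (0 < self.on_path_correlation <= 1):
            raise ParameterError("on_path_correlation must be in (0, 1]")
        if not (0 <= self.off_path_correlation < self.on_path_correlation):
            raise ParameterError("off_path_correlation must be in [0, on_path_correlation)")
        if self.chain_geometry <= 0 or self.displacement_std <= 0 or self.dt <= 0:
            raise ParameterError("geometry, displacement_std and dt must be > 0")
        if self.subunit_split is not None and not (0 < self.subunit_split < n):
            raise ParameterError("subunit_split must split the ring into two non-empty arcs")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")

    def to_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "planted_path": list(self.planted_path),
            "on_path_correlation": self.on_path_correlation,
            "off_path_correlation": self.off_path_correlation,
            "chain_geometry": self.chain_geometry,
            "n_frames": self.n_frames,
            "displacement_std": self.displacement_std,
            "mobile_scale": self.mobile_scale,
            "mobile_residues": list(self.mobile_residues),
            "dt": self.dt,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Ornstein–Uhlenbeck fluctuations
# ---------------------------------------------------------------------------


def simulate_ou(
    theta: float,
    mu: float,
    sigma: float,
    dt: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    x0: float | None = None,
) -> DistanceSeries:
    """Exact-discretization OU trace with stationary std ``sigma``.

    x_{t+dt} = mu + (x_t − mu)·e^{−θ·dt} + sigma·sqrt(1 − e^{−2θ·dt})·Z.

    The update uses the exact discrete solution, so the stationary variance
    sigma² and autocorrelation e^{−θ·τ} hold for any dt.  The initial value
    is drawn from the stationary law unless ``x0`` is given.
    """
    if theta <= 0 or dt <= 0:
        raise ParameterError("theta and dt must be > 0")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    values = np.empty(n)
    values[0] = mu if x0 is None and sigma == 0 else (x0 if x0 is not None else rng.normal(mu, sigma))
    a = np.exp(-theta * dt)
    b = sigma * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal(n - 1)
    x = values[0]
    for i in range(1, n):
        x = mu + (x - mu) * a + b * noise[i - 1]
        values[i] = x
    return DistanceSeries(
        times=dt * np.arange(n),
        values=values,
        pair_label="ou",
        trajectory_id=f"ou_seed{seed}" if seed is not None else "ou",
    )


def _ou_noise(theta: float, sigma: float, dt: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean stationary OU fluctuation of length n (vector form)."""
    if sigma == 0:
        return np.zeros(n)
    a = np.exp(-theta * dt)
    b = sigma * np.sqrt(1.0 - a * a)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma)
    steps = b * rng.standard_normal(n - 1)
    x = out[0]
    for i in range(1, n):
        x = x * a + steps[i - 1]
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# hidden two-state chain
# ---------------------------------------------------------------------------


def sample_two_state_chain(
    k_ab: float, k_ba: float, dt: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Frame-sampled two-state continuous-time Markov chain (0 = A, 1 = B).

    Transition probabilities are the entries of the exact matrix exponential
    exp(Q·dt): p(A→B) = π_B·(1 − e^{−λ·dt}) with λ = k_ab + k_ba and
    π_B = k_ab/λ.  This keeps the stationary occupancy of the discretized
    chain exactly π_A = k_ba/λ at any frame interval; the initial state is
    drawn from the stationary law.
    """
    lam = k_ab + k_ba
    pi_b = k_ab / lam
    decay = 1.0 - np.exp(-lam * dt)
    p_ab = pi_b * decay          # from A to B
    p_ba = (1.0 - pi_b) * decay  # from B to A
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    states[0] = 1 if u[0] < pi_b else 0
    for i in range(1, n):
        s = states[i - 1]
        flip = u[i] < (p_ab if s == 0 else p_ba)
        states[i] = (1 - s) if flip else s
    return states


@dataclass
class SwitchingSample:
    """Generator output: the two distance traces plus the hidden states.

    ``states`` has shape (2, n): row 0 drives the Fe–Fe series, row 1 the
    Fe–Mg series (identical rows when the chains are coupled).  The hidden
    sequence is kept so downstream statistics can be checked against exact
    ground truth.
    """

    fe_fe: DistanceSeries
    fe_mg: DistanceSeries
    states: np.ndarray
    params: SwitchingModelParams

    def __iter__(self):
        return iter((self.fe_fe, self.fe_mg))

    def state_a_fraction(self, series: int = 0) -> float:
        return float(np.mean(self.states[series] == 0))

    def write_sidecar(self, directory: str | Path, stem: str = "switching") -> Path:
        """Persist hidden states (TSV) and generator params (YAML) for provenance."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            {
                "frame": np.arange(self.states.shape[1]),
                "state_fe_fe": self.states[0],
                "state_fe_mg": self.states[1],
            }
        ).to_csv(directory / f"{stem}_states.tsv", sep="\t", index=False)
        (directory / f"{stem}_params.yaml").write_text(yaml.safe_dump(self.params.to_dict()))
        return directory / f"{stem}_states.tsv"


def simulate_switching_distances(params: SwitchingModelParams) -> SwitchingSample:
    """Two-state Markov-switching distance pair with OU fluctuations.

    A hidden chain selects the (Fe–Fe, Fe–Mg) mean pair per frame;
    independent zero-mean OU noise is superimposed on each series; values
    are clamped at 0.1 nm for physical positivity.  With ``coupled=False``
    each series follows its own independent hidden chain (the uncorrelated
    null against which the mutual-exclusion statistic is calibrated).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    chain0 = sample_two_state_chain(params.k_ab, params.k_ba, params.dt, n, rng)
    chain1 = chain0 if params.coupled else sample_two_state_chain(
        params.k_ab, params.k_ba, params.dt, n, rng
    )
    means = np.array([params.mean_a, params.mean_b])  # [state][series]
    fe_fe_vals = means[chain0, 0] + _ou_noise(params.theta, params.sigma, params.dt, n, rng)
    fe_mg_vals = means[chain1, 1] + _ou_noise(params.theta, params.sigma, params.dt, n, rng)
    np.maximum(fe_fe_vals, MIN_DISTANCE_NM, out=fe_fe_vals)
    np.maximum(fe_mg_vals, MIN_DISTANCE_NM, out=fe_mg_vals)
    times = params.dt * np.arange(n)
    fe_fe = DistanceSeries(times=times, values=fe_fe_vals, pair_label="PscC_docked:FE–PscC_distant:FE",
                           trajectory_id=f"switch_seed{params.seed}")
    fe_mg = DistanceSeries(times=times.copy(), values=fe_mg_vals, pair_label="PscC_docked:FE–PscA:MG",
                           trajectory_id=f"switch_seed{params.seed}")
    return SwitchingSample(fe_fe=fe_fe, fe_mg=fe_mg,
                           states=np.vstack([chain0, chain1]), params=params)


# ---------------------------------------------------------------------------
# embedding distances as 3-D marker trajectories
# ---------------------------------------------------------------------------

MARKER_TOPOLOGY = [
    Site("MG", 1, "BCL", "PscA"),
    Site("FE", 1, "HEM", "PscC_docked"),
    Site("FE", 1, "HEM", "PscC_distant"),
]


def embed_distances_as_trajectory(
    fe_fe: DistanceSeries,
    fe_mg: DistanceSeries,
    trajectory_id: str | None = None,
    model_tag: str = "2xPscC",
) -> TrajectoryEnsemble:
    """Place three collinear marker beads reproducing the two distances.

    Per frame: the P840 Mg at the origin, the docked-PscC Fe on +x at the
    Fe–Mg distance, and the distant-PscC Fe collinear beyond it at the Fe–Fe
    distance — so re-extracting distances from coordinates returns the input
    series to floating-point accuracy.
    """
    if fe_fe.n != fe_mg.n:
        raise AlignmentError(f"series lengths differ: {fe_fe.n} vs {fe_mg.n}")
    if not np.allclose(fe_fe.times, fe_mg.times):
        raise AlignmentError("series timestamps differ")
    n = fe_fe.n
    coords = np.zeros((n, 3, 3))
    coords[:, 1, 0] = fe_mg.values
    coords[:, 2, 0] = fe_mg.values + fe_fe.values
    dts = np.diff(fe_fe.times)
    frame_interval = float(dts[0]) if dts.size else 1.0
    traj = Trajectory(
        coords=coords,
        frame_interval=frame_interval,
        t0=float(fe_fe.times[0]),
        times=fe_fe.times.copy(),
        trajectory_id=trajectory_id or fe_fe.trajectory_id or "markers",
        model_tag=model_tag,
    )
    return TrajectoryEnsemble(topology=list(MARKER_TOPOLOGY), trajectories=[traj])


# ---------------------------------------------------------------------------
# planted-correlation network trajectory
# ---------------------------------------------------------------------------

_AROMATIC_CYCLE = ("TRP", "TYR", "PHE")


@dataclass
class PlantedNetworkSample:
    """Generator output: ensemble plus the exact planted structure."""

    ensemble: TrajectoryEnsemble
    correlation: np.ndarray          # requested per-axis correlation matrix
    path_labels: tuple[str, ...]     # node labels of the planted path
    params: PlantedNetworkParams

    def write_sidecar(self, directory: str | Path, stem: str = "planted") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / f"{stem}_correlation.tsv", self.correlation,
                   delimiter="\t", fmt="%.6g")
        (directory / f"{stem}_params.yaml").write_text(yaml.safe_dump(self.params.to_dict()))
        return directory / f"{stem}_params.yaml"


def planted_correlation_matrix(params: PlantedNetworkParams) -> np.ndarray:
    """Requested per-axis bead-displacement correlation matrix.

    Consecutive planted-path beads get ``on_path_correlation``; other
    contacting (ring-neighbour) pairs get ``off_path_correlation``.  Within
    the planted path the correlation decays geometrically with path
    separation (``on^|i−j|``, the Markov/AR(1) profile): a high
    consecutive-pair correlation with zero beyond the neighbours is not a
    valid (positive-semidefinite) correlation structure, whereas the
    geometric decay is, while leaving every pairwise value the generator
    guarantees unchanged.
    """
    n = params.n_residues
    R = np.eye(n)
    pos = {b: k for k, b in enumerate(params.planted_path)}
    for i in range(n):
        j = (i + 1) % n
        if i in pos and j in pos and abs(pos[i] - pos[j]) == 1:
            r = params.on_path_correlation
        else:
            r = params.off_path_correlation
        R[i, j] = R[j, i] = r
    for a in pos:
        for b in pos:
            k = abs(pos[a] - pos[b])
            if k > 1:
                R[a, b] = R[b, a] = params.on_path_correlation**k
    return R


def generate_planted_network_trajectory(params: PlantedNetworkParams) -> PlantedNetworkSample:
    """Bead-ring trajectory whose displacement correlations are known exactly.

    Rest positions lie on a circle with neighbour spacing ``chain_geometry``;
    zero-mean Gaussian displacements with the planted correlation matrix
    (identical and independent across the three axes) are added per frame.
    A non-positive-semidefinite request raises with the offending eigenvalue.
    """
    R = planted_correlation_matrix(params)
    eigvals = np.linalg.eigvalsh(R)
    if eigvals[0] < -1e-10:
        raise ParameterError(
            f"requested correlation matrix is not positive semidefinite "
            f"(minimum eigenvalue {eigvals[0]:.4g})"
        )
    n = params.n_residues
    # symmetric PSD square root; tolerates exactly-singular requests
    w, V = np.linalg.eigh(R)
    A = V * np.sqrt(np.clip(w, 0.0, None))

    radius = params.chain_geometry / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    rest = np.column_stack([radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)])

    stds = np.full(n, params.displacement_std)
    if params.mobile_residues:
        stds[list(params.mobile_residues)] *= params.mobile_scale

    rng = np.random.default_rng(params.seed)
    coords = np.empty((params.n_frames, n, 3))
    for axis in range(3):
        Z = rng.standard_normal((params.n_frames, n))
        coords[:, :, axis] = rest[None, :, axis] + (Z @ A.T) * stds[None, :]

    on_path = set(params.planted_path)
    arom = {b: _AROMATIC_CYCLE[k % 3] for k, b in enumerate(params.planted_path)}
    split = params.subunit_split

    def subunit_resid(i: int) -> tuple[str, int]:
        # with subunit_split the two arcs mimic two domains sharing a residue
        # numbering (e.g. the TMH range of each cytochrome copy)
        if split is None:
            return "NET", i + 1
        return ("RINGA", i + 1) if i < split else ("RINGB", i - split + 1)

    topology = [
        Site("CA", subunit_resid(i)[1], arom[i] if i in on_path else "ALA", subunit_resid(i)[0])
        for i in range(n)
    ]
    traj = Trajectory(
        coords=coords,
        frame_interval=params.dt,
        trajectory_id=f"planted_seed{params.seed}",
        model_tag="planted_ring",
    )
    labels = tuple("{}:{}".format(*subunit_resid(i)) for i in params.planted_path)
    return PlantedNetworkSample(
        ensemble=TrajectoryEnsemble(topology=topology, trajectories=[traj]),
        correlation=R,
        path_labels=labels,
        params=params,
    )
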