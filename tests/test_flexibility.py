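"""Superposition and flexibility: rigid-motion invariance, an independent
rotation-search oracle, RMSF closed forms and mobility comparisons."""

import numpy as np
import pytest
import scipy.optimize
from scipy.spatial.transform import Rotation

from corrshuttle import (
    Site,
    Trajectory,
    TrajectoryEnsemble,
    flexibility_compare,
    flexibility_profile,
    rmsd_series,
    rmsf_profile,
    superpose,
)
from corrshuttle.exceptions import DataError, DegenerateFitError
from tests.conftest import random_rotation


def oracle_min_rmsd(mobile, ref):
    """Independent oracle: coarse Euler-angle grid + Nelder-Mead refinement.

    Centroids are aligned analytically; only the rotation is searched, via
    scipy's Rotation rather than the package's SVD solver.
    """
    P = mobile - mobile.mean(axis=0)
    Q = ref - ref.mean(axis=0)

    def rmsd_at(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, 13)
    best, best_angles = np.inf, None
    for a in grid:
        for b in np.linspace(-np.pi / 2, np.pi / 2, 7):
            for c in grid:
                v = rmsd_at((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = scipy.optimize.minimize(rmsd_at, best_angles, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    return min(best, float(res.fun))


def chain_frame(n=8, spacing=0.4):
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    coords[::2, 1] = 0.25
    coords[1::3, 2] = 0.1
    return coords


class TestSuperpose:
    def test_self_fit_is_identity_with_zero_rmsd(self):
        frame = chain_frame()
        fitted, rmsd = superpose(frame, frame)
        assert rmsd <= 1e-12
        np.testing.assert_allclose(fitted, frame, atol=1e-12)

    def test_rigid_transform_recovers_zero_rmsd(self, rng):
        frame = chain_frame()
        moved = frame @ random_rotation(rng).T + rng.normal(size=3)
        _fitted, rmsd = superpose(moved, frame)
        assert rmsd <= 1e-10

    @pytest.mark.parametrize("case", [0, 1])
    def test_matches_rotation_search_oracle_on_four_point_fixtures(self, case):
        fixtures = [
            (
                np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 0.9]]),
                np.array([[0.05, 0, 0], [0.9, 0.2, 0], [0.1, 1.1, -0.1], [0.4, 0.1, 1.0]]),
            ),
            (
                np.array([[0.0, 0, 0], [0.5, 0.1, 0], [0.2, 0.6, 0.1], [0.7, 0.7, 0.7]]),
                np.array([[0.1, -0.1, 0], [0.6, 0.0, 0.1], [0.15, 0.7, 0.0], [0.6, 0.6, 0.8]]),
            ),
        ]
        mobile, ref = fixtures[case]
        _fitted, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(oracle_min_rmsd(mobile, ref), abs=1e-4)
        assert rmsd <= oracle_min_rmsd(mobile, ref) + 1e-9  # ours is the optimum

    def test_rmsd_invariant_to_prior_rigid_motion(self, rng):
        frame = chain_frame()
        target = frame + rng.normal(0, 0.05, frame.shape)
        _f, rmsd0 = superpose(frame, target)
        moved = frame @ random_rotation(rng).T + rng.normal(size=3)
        _f, rmsd1 = superpose(moved, target)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-10)

    def test_too_few_or_collinear_sites_rejected(self):
        with pytest.raises(DegenerateFitError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.zeros((5, 3))
        line[:, 0] = np.arange(5.0)
        with pytest.raises(DegenerateFitError):
            superpose(line, line)


def jitter_ensemble(rng, n_frames=100_000, n_beads=16, sigma=0.05, jittered=5):
    rest = chain_frame(n_beads)
    coords = np.repeat(rest[None], n_frames, axis=0)
    coords[:, jittered, :] += rng.normal(0, sigma, (n_frames, 3))
    topo = [Site("CA", i + 1, "ALA", "NET") for i in range(n_beads)]
    return TrajectoryEnsemble(topo, [Trajectory(coords, 0.1)])


class TestRmsdSeries:
    def test_identical_frames_give_zero_everywhere(self, bead_chain_ensemble):
        df = rmsd_series(bead_chain_ensemble, "NET")
        assert np.allclose(df["rmsd_nm"], 0.0, atol=1e-12)

    def test_matches_per_frame_superpose(self, rng):
        ens = jitter_ensemble(rng, n_frames=50)
        df = rmsd_series(ens, "NET", reference="first")
        ref = ens.trajectories[0].coords[0]
        for k in range(50):
            _f, r = superpose(ens.trajectories[0].coords[k], ref)
            assert df["rmsd_nm"].iloc[k] == pytest.approx(r, abs=1e-12)

    def test_planted_variance_orders_rmsd_distributions(self, rng):
        n = 2000
        rest = chain_frame(16)
        coords = np.repeat(rest[None], n, axis=0)
        coords[:, :8, :] += rng.normal(0, 0.02, (n, 8, 3))   # stable half
        coords[:, 8:, :] += rng.normal(0, 0.08, (n, 8, 3))   # mobile half
        topo = [Site("CA", i % 8 + 1, "ALA", "DOCK" if i < 8 else "DIST") for i in range(16)]
        ens = TrajectoryEnsemble(topo, [Trajectory(coords, 0.1)])
        low = rmsd_series(ens, "DOCK")["rmsd_nm"]
        high = rmsd_series(ens, "DIST")["rmsd_nm"]
        assert np.median(high) > np.median(low)


class TestRmsf:
    def test_static_beads_have_zero_rmsf(self, bead_chain_ensemble):
        rmsf = rmsf_profile(bead_chain_ensemble, "NET")
        assert np.allclose(rmsf.to_numpy(), 0.0, atol=1e-12)

    def test_isotropic_jitter_closed_form(self, rng):
        # static beads pin the fit; jittered bead fluctuates sigma*sqrt(3)
        ens = jitter_ensemble(rng, sigma=0.05, jittered=5)
        static = [i for i in range(16) if i != 5]
        rmsf = rmsf_profile(ens, "NET", fit_selection=static)
        assert rmsf.loc[6] == pytest.approx(0.05 * np.sqrt(3), rel=0.03)
        assert rmsf.drop(6).max() <= 1e-9

    def test_planted_variance_ratio_carries_to_rmsf(self, rng):
        n = 20_000
        rest = chain_frame(12)
        coords = np.repeat(rest[None], n, axis=0)
        coords[:, :6, :] += rng.normal(0, 0.02, (n, 6, 3))
        coords[:, 6:, :] += rng.normal(0, 0.04, (n, 6, 3))  # planted 4:1 variance
        topo = [Site("CA", i + 1, "ALA", "NET") for i in range(12)]
        ens = TrajectoryEnsemble(topo, [Trajectory(coords, 0.1)])
        rmsf = rmsf_profile(ens, "NET")
        ratio = rmsf.loc[7:12].mean() / rmsf.loc[1:6].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_frame_order_invariance(self, rng):
        ens = jitter_ensemble(rng, n_frames=500)
        rmsf_a = rmsf_profile(ens, "NET")
        perm = rng.permutation(500)
        ens_b = TrajectoryEnsemble(
            ens.topology, [Trajectory(ens.trajectories[0].coords[perm], 0.1)]
        )
        rmsf_b = rmsf_profile(ens_b, "NET")
        np.testing.assert_allclose(rmsf_a.to_numpy(), rmsf_b.to_numpy(), atol=1e-9)

    def test_single_frame_rejected(self):
        topo = [Site("CA", i + 1, "ALA", "NET") for i in range(4)]
        ens = TrajectoryEnsemble(topo, [Trajectory(chain_frame(4)[None], 0.1)])
        with pytest.raises(DataError):
            rmsf_profile(ens, "NET")


class TestCompare:
    def _two_profile_ensemble(self, rng, ratio=2.0):
        n = 5000
        rest = chain_frame(16)
        coords = np.repeat(rest[None], n, axis=0)
        coords[:, :8, :] += rng.normal(0, 0.02, (n, 8, 3))
        coords[:, 8:, :] += rng.normal(0, 0.02 * ratio, (n, 8, 3))
        topo = [Site("CA", i % 8 + 1, "ALA", "DOCK" if i < 8 else "DIST") for i in range(16)]
        ens = TrajectoryEnsemble(topo, [Trajectory(coords, 0.1)])
        return (
            flexibility_profile(ens, "DOCK"),
            flexibility_profile(ens, "DIST"),
        )

    def test_identical_profiles_tie(self, rng):
        p, _q = self._two_profile_ensemble(rng)
        cmp = flexibility_compare(p, p)
        assert cmp["more_mobile"] == "tie"
        assert np.allclose(cmp["rmsf_diff_nm"].to_numpy(), 0.0)

    def test_planted_variance_names_mobile_selection(self, rng):
        docked, distant = self._two_profile_ensemble(rng, ratio=2.0)
        cmp = flexibility_compare(docked, distant)
        assert cmp["more_mobile"] == "DIST"

    def test_swap_negates_differences(self, rng):
        docked, distant = self._two_profile_ensemble(rng)
        ab = flexibility_compare(docked, distant)["rmsf_diff_nm"]
        ba = flexibility_compare(distant, docked)["rmsf_diff_nm"]
        np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy(), atol=1e-12)
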