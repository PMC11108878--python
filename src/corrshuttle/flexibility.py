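"""Backbone superposition and flexibility profiling (RMSD / RMSF).

The least-squares rigid-body fit (Kabsch) is implemented directly so it can
run batched over whole frame stacks with a single stacked SVD; reflections
are excluded (proper rotations only).  Per-frame RMSD is computed after
fitting each frame onto a reference over the measured selection; per-residue
RMSF uses the standard iterative mean-structure procedure: frames are
refitted to their running mean structure until the mean stops moving, then
RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩).

The motivating comparison is between the transmembrane helices (residues
1–100) of the docked and the distant cytochrome domains: the docked one is
expected to be the structurally stabler of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, DegenerateFitError, ParameterError
from .trajectory import TrajectoryEnsemble, resolve_selection


# ---------------------------------------------------------------------------
# Kabsch core
# ---------------------------------------------------------------------------


def _check_fit_points(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError(f"need >= 3 sites to fit, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise DegenerateFitError("fit sites are collinear; rotation is underdetermined")


def _batch_rotations(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotations R_m minimizing Σ|R_m p_mn − q_n|² (inputs centered).

    P: (m, n, 3) stack of centered mobile selections; Q: (n, 3) centered
    reference.  Returns (m, 3, 3).
    """
    H = np.einsum("mni,nj->mij", P, Q)
    U, _S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("mji,mkj->mik", Vt, U))  # det(V @ U^T)
    D = np.repeat(np.eye(3)[None], P.shape[0], axis=0)
    D[:, 2, 2] = np.sign(det)
    return np.einsum("mji,mjk,mlk->mil", Vt, D, U)  # V @ D @ U^T


def superpose(
    mobile_frame: np.ndarray,
    reference_frame: np.ndarray,
    fit_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid fit of one frame onto a reference.

    The rotation/translation is determined on ``fit_idx`` (default: all
    sites) and applied to the whole frame; the returned RMSD (nm) is over the
    fit selection.  Fewer than three or collinear fit sites raise
    :class:`DegenerateFitError`.
    """
    mobile = np.asarray(mobile_frame, dtype=float)
    ref = np.asarray(reference_frame, dtype=float)
    if mobile.shape != ref.shape:
        raise ParameterError(f"frame shapes differ: {mobile.shape} vs {ref.shape}")
    idx = np.arange(mobile.shape[0]) if fit_idx is None else np.asarray(fit_idx, dtype=int)
    _check_fit_points(mobile[idx])
    _check_fit_points(ref[idx])
    mc = mobile[idx].mean(axis=0)
    rc = ref[idx].mean(axis=0)
    R = _batch_rotations((mobile[idx] - mc)[None], ref[idx] - rc)[0]
    fitted = (mobile - mc) @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted[idx] - ref[idx]) ** 2, axis=1))))
    return fitted, rmsd


def _batch_superpose(
    frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fit every frame onto the reference; returns (fitted frames, rmsd array)."""
    _check_fit_points(reference[fit_idx])
    sel = frames[:, fit_idx, :]
    mc = sel.mean(axis=1, keepdims=True)          # (m, 1, 3)
    rc = reference[fit_idx].mean(axis=0)
    R = _batch_rotations(sel - mc, reference[fit_idx] - rc)
    fitted = np.einsum("mij,mnj->mni", R, frames - mc) + rc
    diff = fitted[:, fit_idx, :] - reference[fit_idx]
    rmsd = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return fitted, rmsd


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class FlexibilityProfile:
    """Per-frame RMSD and per-residue RMSF for one selection."""

    selection: str
    rmsd: pd.DataFrame              # columns: trajectory_id, frame, time_ns, rmsd_nm
    rmsf: pd.Series                 # index: resid (1-based), values nm
    reference: str                  # "first" or "mean"

    @property
    def rmsd_values(self) -> np.ndarray:
        return self.rmsd["rmsd_nm"].to_numpy()


def _pooled(ensemble: TrajectoryEnsemble):
    frames = ensemble.pooled_coords()
    meta = []
    for traj in ensemble.trajectories:
        for k in range(traj.n_frames):
            meta.append((traj.trajectory_id, k, float(traj.times[k])))
    return frames, meta


def mean_structure(
    ensemble: TrajectoryEnsemble,
    selection,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative mean structure after repeated refitting of all frames.

    Returns (fitted pooled frames, converged mean coordinates).  The mean
    displacement between successive mean structures decreases monotonically
    to below ``tol`` (nm) on well-posed inputs; iteration stops at
    ``max_iter`` regardless.
    """
    fit_idx = resolve_selection(ensemble.topology, selection)
    frames, _meta = _pooled(ensemble)
    if frames.shape[0] < 2:
        raise DataError("need >= 2 frames to define fluctuations")
    ref = frames[0].copy()
    fitted = frames
    for _ in range(max_iter):
        fitted, _ = _batch_superpose(frames, ref, fit_idx)
        new_ref = fitted.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_ref[fit_idx] - ref[fit_idx], axis=1)))
        ref = new_ref
        if shift < tol:
            break
    return fitted, ref


def rmsd_series(
    ensemble: TrajectoryEnsemble,
    selection,
    reference: str = "first",
    fit_selection=None,
) -> pd.DataFrame:
    """Per-frame RMSD over ``selection`` after fitting each frame on it.

    ``reference`` is "first" (first frame of the first trajectory, i.e. the
    first analyzed frame after any trimming) or "mean" (iterative mean
    structure).  ``fit_selection`` allows fitting on a different selection
    than the one measured (default: same).
    """
    meas_idx = resolve_selection(ensemble.topology, selection)
    fit_idx = meas_idx if fit_selection is None else resolve_selection(ensemble.topology, fit_selection)
    frames, meta = _pooled(ensemble)
    if isinstance(reference, str):
        if reference == "first":
            ref = frames[0]
        elif reference == "mean":
            _, ref = mean_structure(ensemble, selection if fit_selection is None else fit_selection)
        else:
            raise ParameterError(f"unknown reference {reference!r} (use 'first' or 'mean')")
    else:
        ref = np.asarray(reference, dtype=float)
    fitted, _ = _batch_superpose(frames, ref, fit_idx)
    diff = fitted[:, meas_idx, :] - ref[meas_idx]
    rmsd = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    df = pd.DataFrame(meta, columns=["trajectory_id", "frame", "time_ns"])
    df["rmsd_nm"] = rmsd
    return df


def rmsf_profile(ensemble: TrajectoryEnsemble, selection, fit_selection=None) -> pd.Series:
    """Per-residue RMSF (nm) about the iterative mean structure.

    Frames are pooled over all trajectories; the fit is performed on
    ``fit_selection`` (default: the measured selection itself).  For
    residues represented by several sites the root-mean-square over the
    residue's sites is reported.
    """
    meas_idx = resolve_selection(ensemble.topology, selection)
    fitted, ref = mean_structure(ensemble, selection if fit_selection is None else fit_selection)
    dev2 = np.sum((fitted[:, meas_idx, :] - ref[meas_idx]) ** 2, axis=2)  # (m, n_sel)
    msf = dev2.mean(axis=0)
    resids = np.array([ensemble.topology[i].resid for i in meas_idx])
    per_res = pd.Series(msf).groupby(resids).mean()
    return pd.Series(np.sqrt(per_res.to_numpy()), index=per_res.index.astype(int), name="rmsf_nm")


def flexibility_profile(
    ensemble: TrajectoryEnsemble,
    selection,
    reference: str = "first",
    fit_selection=None,
) -> FlexibilityProfile:
    """Convenience bundle of RMSD series and RMSF profile for one selection."""
    sel_str = selection if isinstance(selection, str) else repr(selection)
    return FlexibilityProfile(
        selection=sel_str,
        rmsd=rmsd_series(ensemble, selection, reference=reference, fit_selection=fit_selection),
        rmsf=rmsf_profile(ensemble, selection, fit_selection=fit_selection),
        reference=reference if isinstance(reference, str) else "explicit",
    )


def flexibility_compare(
    profile_docked: FlexibilityProfile, profile_distant: FlexibilityProfile
) -> dict:
    """Per-residue RMSF differences and a mobility verdict.

    Differences are second minus first (swap negates them); the verdict
    names the selection with the larger median RMSF, or "tie" when equal.
    """
    a, b = profile_docked.rmsf, profile_distant.rmsf
    if not a.index.equals(b.index):
        raise ParameterError(
            f"profiles cover different residue ranges: "
            f"{a.index.min()}-{a.index.max()} vs {b.index.min()}-{b.index.max()}"
        )
    diff = b - a
    med_a, med_b = float(a.median()), float(b.median())
    if med_a == med_b:
        verdict = "tie"
    else:
        verdict = profile_distant.selection if med_b > med_a else profile_docked.selection
    return {
        "rmsf_diff_nm": diff,
        "median_rmsf_nm": {profile_docked.selection: med_a, profile_distant.selection: med_b},
        "median_rmsd_nm": {
            profile_docked.selection: float(np.median(profile_docked.rmsd_values)),
            profile_distant.selection: float(np.median(profile_distant.rmsd_values)),
        },
        "more_mobile": verdict,
    }
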