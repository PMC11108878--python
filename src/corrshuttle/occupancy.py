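"""Mutually-exclusive distance-occupancy statistic swept over (C, d).

The statistic quantifies anticorrelated alternation of the two key
distances: the fraction of frames in which the PscC–PscC distance is below
C·d while the PscA–PscC distance exceeds d, or vice versa (strict
inequalities; a frame on a threshold counts for neither branch).  Sweeping
the threshold d for a family of contraction factors C yields the occupancy
curves; their peaks summarize at which distance pairs the mutually-exclusive
configurations concentrate, and the two-vector projection tags each frame
with its (C, d) membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import AlignmentError, ParameterError
from .trajectory import DistanceSeries

DEFAULT_C_LIST = tuple(np.round(np.arange(67, 101) / 100.0, 2))
DEFAULT_D_GRID = tuple(np.round(np.arange(150, 451) / 100.0, 2))


def _values(series) -> np.ndarray:
    if isinstance(series, DistanceSeries):
        return series.values
    return np.asarray(series, dtype=float)


def _aligned_pair(d1, d2) -> tuple[np.ndarray, np.ndarray]:
    v1, v2 = _values(d1), _values(d2)
    if v1.shape != v2.shape:
        raise AlignmentError(f"series are not frame-aligned: {v1.shape} vs {v2.shape}")
    if v1.size == 0:
        raise ParameterError("empty series")
    return v1, v2


@dataclass
class OccupancyCurve:
    """Occupancy fraction versus threshold d for one contraction factor C."""

    C: float
    d_grid: np.ndarray
    fraction: np.ndarray
    n_frames: int
    pair_labels: tuple[str, str] = ("PscC–PscC", "PscA–PscC")

    def __post_init__(self) -> None:
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.d_grid.shape != self.fraction.shape:
            raise ParameterError("d_grid and fraction must have equal length")
        if np.any(np.diff(self.d_grid) <= 0):
            raise ParameterError("d_grid must be strictly increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ParameterError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class PeakRecord:
    """One local maximum of an occupancy curve."""

    C: float
    d_peak: float
    fraction_at_peak: float

    @property
    def low_threshold(self) -> float:
        return self.C * self.d_peak


def exclusion_fraction(d1, d2, d: float, C: float = 1.0) -> float:
    """Fraction of frames in either mutually-exclusive branch at (C, d).

    Branch one: D1 < C·d and D2 > d.  Branch two: D1 > d and D2 < C·d.
    Frame order is irrelevant; strict inequalities throughout.
    """
    if not (0 < C <= 1):
        raise ParameterError(f"C must be in (0, 1], got {C}")
    if d <= 0:
        raise ParameterError(f"d must be > 0, got {d}")
    v1, v2 = _aligned_pair(d1, d2)
    cd = C * d
    hit = ((v1 < cd) & (v2 > d)) | ((v1 > d) & (v2 < cd))
    return float(np.mean(hit))


def occupancy_curves(
    d1,
    d2,
    d_grid: Sequence[float] | None = None,
    C_list: Sequence[float] | None = None,
    pair_labels: tuple[str, str] | None = None,
) -> list[OccupancyCurve]:
    """One occupancy curve per contraction factor C.

    Defaults: C ∈ {0.67, 0.68, …, 1.00} (34 curves) and d ∈ [1.5, 4.5] nm in
    0.01 nm steps.  The sweep is evaluated in d-chunks so the frame × grid
    boolean masks stay small.
    """
    v1, v2 = _aligned_pair(d1, d2)
    d_arr = np.asarray(DEFAULT_D_GRID if d_grid is None else d_grid, dtype=float)
    c_arr = np.asarray(DEFAULT_C_LIST if C_list is None else C_list, dtype=float)
    if d_arr.size == 0 or c_arr.size == 0:
        raise ParameterError("d_grid and C_list must be non-empty")
    if np.any(d_arr <= 0) or np.any((c_arr <= 0) | (c_arr > 1)):
        raise ParameterError("d values must be > 0 and C values in (0, 1]")
    if pair_labels is None:
        pair_labels = (
            getattr(d1, "pair_label", "") or "PscC–PscC",
            getattr(d2, "pair_label", "") or "PscA–PscC",
        )
    n = v1.size
    curves = []
    chunk = max(1, int(4e6 // max(n, 1)) or 1)
    for c in c_arr:
        frac = np.empty(d_arr.size)
        for lo in range(0, d_arr.size, chunk):
            dc = d_arr[lo : lo + chunk][None, :]
            b1 = (v1[:, None] < c * dc) & (v2[:, None] > dc)
            b2 = (v1[:, None] > dc) & (v2[:, None] < c * dc)
            frac[lo : lo + dc.shape[1]] = np.mean(b1 | b2, axis=0)
        curves.append(
            OccupancyCurve(C=float(c), d_grid=d_arr.copy(), fraction=frac,
                           n_frames=n, pair_labels=pair_labels)
        )
    return curves


def find_peaks(curve: OccupancyCurve, min_prominence: float = 0.02) -> list[PeakRecord]:
    """Interior local maxima of one curve, sorted by height (ties: smaller d).

    Prominence is measured on the occupancy-fraction scale; the default 0.02
    (two percentage points) suppresses grid-level ripples.  For plateau
    maxima the left edge (smaller d) is reported.
    """
    y = curve.fraction
    if y.size == 0:
        return []
    idx, props = scipy.signal.find_peaks(y, prominence=min_prominence, plateau_size=(1, None))
    positions = props.get("left_edges", idx)
    records = [
        PeakRecord(C=curve.C, d_peak=float(curve.d_grid[p]), fraction_at_peak=float(y[p]))
        for p in positions
    ]
    records.sort(key=lambda r: (-r.fraction_at_peak, r.d_peak))
    return records


def table_report(
    curves: Sequence[OccupancyCurve],
    C_subset: Sequence[float] | None = None,
    min_prominence: float = 0.02,
) -> pd.DataFrame:
    """Peak table with one row per (C, peak): threshold pair and percent time.

    Columns: C, d_peak_nm, low_threshold_nm (= C·d_peak) and percent — the
    percentage of pooled frames in the mutually-exclusive configurations at
    that threshold pair.
    """
    by_c = {round(c.C, 6): c for c in curves}
    if C_subset is None:
        wanted = list(by_c)
    else:
        wanted = []
        for c in C_subset:
            key = round(float(c), 6)
            if key not in by_c:
                raise KeyError(f"C={c} was not computed; available: {sorted(by_c)}")
            wanted.append(key)
    rows = []
    for key in wanted:
        curve = by_c[key]
        for rec in find_peaks(curve, min_prominence=min_prominence):
            rows.append(
                {
                    "C": rec.C,
                    "d_peak_nm": rec.d_peak,
                    "low_threshold_nm": round(rec.low_threshold, 6),
                    "percent": 100.0 * rec.fraction_at_peak,
                }
            )
    return pd.DataFrame(rows, columns=["C", "d_peak_nm", "low_threshold_nm", "percent"])


def curves_to_frame(curves: Sequence[OccupancyCurve]) -> pd.DataFrame:
    """Long-form (C, d_nm, fraction) table for TSV export."""
    parts = [
        pd.DataFrame({"C": c.C, "d_nm": c.d_grid, "fraction": c.fraction}) for c in curves
    ]
    return pd.concat(parts, ignore_index=True)


def project_frames(d1, d2) -> pd.DataFrame:
    """Scatter-ready per-frame table of the two distances (one row per frame)."""
    v1, v2 = _aligned_pair(d1, d2)
    return pd.DataFrame({"frame": np.arange(v1.size), "d1_nm": v1, "d2_nm": v2})


def flag_membership(cloud: pd.DataFrame, C: float, d: float) -> np.ndarray:
    """Boolean per-frame membership in either branch at (C, d).

    The flag count over n_frames equals ``exclusion_fraction`` at the same
    (C, d) by construction (same predicate).  A membership column is also
    added to ``cloud`` in place.
    """
    if not (0 < C <= 1) or d <= 0:
        raise ParameterError("need 0 < C <= 1 and d > 0")
    v1 = cloud["d1_nm"].to_numpy()
    v2 = cloud["d2_nm"].to_numpy()
    cd = C * d
    member = ((v1 < cd) & (v2 > d)) | ((v1 > d) & (v2 < cd))
    cloud[f"member_C{C:g}_d{d:g}"] = member
    return member
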