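"""Trajectory containers, file I/O, site selection and distance extraction.

Internal units are nm for coordinates/distances and ns for times throughout
the package; PDB files on disk use Å as the format mandates.

The central containers are :class:`TrajectoryEnsemble` — a set of independent
multi-frame bead/atom trajectories sharing one topology with subunit/residue
labels (e.g. the docked and distant PscC cytochrome domains around the PscA
core) — and :class:`DistanceSeries`, a timestamped scalar distance trace for
one marker pair (heme Fe to heme Fe, or heme Fe to the P840 Mg).

File formats (multi-model PDB, XYZ) are read and written through MDAnalysis.
PDB chain identifiers are a single character, so the full subunit labels are
carried in a small JSON sidecar written next to each file; reading falls back
to chain identifiers when no sidecar is present.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptyTrajectoryError,
    FormatError,
    LabelError,
    ParameterError,
    SelectionError,
    StructureError,
)

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Site:
    """One labeled site (bead or atom) of the shared topology.

    Residue indices are 1-based, matching the convention used for selections
    like the transmembrane-helix range "residues 1-100".
    """

    name: str
    resid: int
    resname: str = "UNK"
    subunit: str = "A"

    def __post_init__(self) -> None:
        if self.resid < 1:
            raise ParameterError(f"residue index must be >= 1, got {self.resid}")

    @property
    def label(self) -> str:
        return f"{self.subunit}:{self.resid}:{self.name}"


@dataclass
class Trajectory:
    """One independent multi-frame trajectory.

    ``coords`` has shape (n_frames, n_sites, 3) in nm.  ``times`` is explicit
    (ns) so trimming composes exactly; ``t_origin`` is the nominal start used
    by :func:`trim_equilibration` and advances by the discarded span rather
    than snapping to the first kept frame, so trim(t1) ∘ trim(t2) equals
    trim(t1 + t2).
    """

    coords: np.ndarray
    frame_interval: float
    t0: float = 0.0
    trajectory_id: str = "traj"
    model_tag: str = ""
    times: np.ndarray | None = None
    t_origin: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must have shape (n_frames, n_sites, 3), got {self.coords.shape}"
            )
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0 ns")
        if self.times is None:
            self.times = self.t0 + self.frame_interval * np.arange(self.n_frames)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise StructureError("times length must match frame count")
        if self.t_origin is None:
            self.t_origin = float(self.times[0]) if self.n_frames else self.t0

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    @property
    def sampled_time(self) -> float:
        """Sampled span in ns, counting each frame as one frame interval."""
        return self.n_frames * self.frame_interval


@dataclass
class TrajectoryEnsemble:
    """Independent trajectories sharing one labeled topology."""

    topology: list[Site]
    trajectories: list[Trajectory]

    def __post_init__(self) -> None:
        n = len(self.topology)
        for traj in self.trajectories:
            if traj.n_sites != n:
                raise StructureError(
                    f"trajectory {traj.trajectory_id!r} has {traj.n_sites} sites, "
                    f"topology has {n}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.topology)

    @property
    def n_frames_total(self) -> int:
        return sum(t.n_frames for t in self.trajectories)

    def pooled_coords(self) -> np.ndarray:
        """All frames of all trajectories stacked, shape (sum n_frames, n_sites, 3)."""
        return np.concatenate([t.coords for t in self.trajectories], axis=0)


@dataclass
class DistanceSeries:
    """Timestamped scalar distance trace for one marker pair.

    ``boundaries`` holds the frame indices where concatenated trajectories
    join (the start index of each segment after the first), so that
    autocorrelation-aware statistics can exclude cross-boundary pairs.
    Frame-wise statistics ignore the boundaries.
    """

    times: np.ndarray
    values: np.ndarray
    pair_label: str = ""
    trajectory_id: str = ""
    boundaries: tuple[int, ...] = ()
    t_origin: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise AlignmentError("times and values must be 1-D and equal length")
        if self.n and np.any(self.values <= 0):
            warnings.warn(
                f"{self.pair_label or 'series'}: {int(np.sum(self.values <= 0))} "
                "non-positive distance value(s)",
                stacklevel=2,
            )
        if self.t_origin is None and self.n:
            self.t_origin = float(self.times[0])

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def segment_index(self) -> np.ndarray:
        """Per-frame segment number (0-based) implied by ``boundaries``."""
        return np.searchsorted(np.asarray(self.boundaries), np.arange(self.n), side="right")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "distance_nm": self.values,
                "trajectory_id": self.trajectory_id,
                "segment_index": self.segment_index(),
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, pair_label: str = "") -> "DistanceSeries":
        df = pd.read_csv(path, sep="\t")
        seg = df["segment_index"].to_numpy()
        boundaries = tuple(int(i) for i in np.flatnonzero(np.diff(seg) > 0) + 1)
        tid = str(df["trajectory_id"].iloc[0]) if len(df) else ""
        return cls(
            times=df["time_ns"].to_numpy(),
            values=df["distance_nm"].to_numpy(),
            pair_label=pair_label,
            trajectory_id=tid,
            boundaries=boundaries,
        )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def resolve_selection(topology: Sequence[Site], selector) -> np.ndarray:
    """Resolve a selector to site indices.

    Selectors may be: an int or sequence of ints (site indices); a dict with
    any of the keys ``subunit``, ``resid`` (int or (lo, hi) range), ``name``,
    ``resname``; or a colon-separated string whose tokens are classified as a
    residue index (``"12"``), a residue range (``"1-100"``), a subunit label
    (if it matches one present in the topology), or a site name — e.g.
    ``"PscC_docked:FE"`` or ``"PscC_distant:1-100"``.
    """
    if isinstance(selector, (int, np.integer)):
        return np.array([int(selector)])
    if isinstance(selector, (list, tuple, np.ndarray)) and not isinstance(selector, str):
        return np.asarray(selector, dtype=int)

    crit: dict = {}
    if isinstance(selector, dict):
        crit = dict(selector)
    elif isinstance(selector, str):
        subunits = {s.subunit for s in topology}
        for tok in selector.split(":"):
            tok = tok.strip()
            if not tok:
                continue
            if tok.isdigit():
                crit["resid"] = int(tok)
            elif "-" in tok and all(p.isdigit() for p in tok.split("-", 1)):
                lo, hi = tok.split("-", 1)
                crit["resid"] = (int(lo), int(hi))
            elif tok in subunits:
                crit["subunit"] = tok
            else:
                crit["name"] = tok
    else:
        raise SelectionError(f"unsupported selector type: {type(selector).__name__}")

    def matches(site: Site) -> bool:
        if "subunit" in crit and site.subunit != crit["subunit"]:
            return False
        if "name" in crit and site.name != crit["name"]:
            return False
        if "resname" in crit and site.resname != crit["resname"]:
            return False
        if "resid" in crit:
            r = crit["resid"]
            if isinstance(r, tuple):
                if not (r[0] <= site.resid <= r[1]):
                    return False
            elif site.resid != r:
                return False
        return True

    idx = np.array([i for i, s in enumerate(topology) if matches(s)], dtype=int)
    if idx.size == 0:
        available = sorted({s.subunit for s in topology})
        raise SelectionError(
            f"selector {selector!r} matched no sites; subunits present: {available}"
        )
    return idx


def resolve_single_site(topology: Sequence[Site], selector) -> int:
    idx = resolve_selection(topology, selector)
    if idx.size != 1:
        cands = [topology[i].label for i in idx[:10]]
        raise SelectionError(
            f"selector {selector!r} must match exactly one site, matched {idx.size}: {cands}"
        )
    return int(idx[0])


# ---------------------------------------------------------------------------
# file I/O (via MDAnalysis)
# ---------------------------------------------------------------------------

_CHAIN_LETTERS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".sites.json")


def _topology_to_json(topology: Sequence[Site]) -> list[dict]:
    return [
        {"name": s.name, "resid": s.resid, "resname": s.resname, "subunit": s.subunit}
        for s in topology
    ]


def _topology_from_json(records: Iterable[dict]) -> list[Site]:
    return [Site(r["name"], int(r["resid"]), r.get("resname", "UNK"), r.get("subunit", "A")) for r in records]


def _universe_from(topology: Sequence[Site], coords_nm: np.ndarray):
    """Build an in-memory MDAnalysis Universe (coordinates in Å)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = len(topology)
    # group sites into residues by (subunit, resid), preserving order
    res_keys: list[tuple[str, int]] = []
    atom_resindex = np.empty(n_atoms, dtype=int)
    for i, s in enumerate(topology):
        key = (s.subunit, s.resid)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    subunits: list[str] = []
    residue_segindex = np.empty(len(res_keys), dtype=int)
    for j, (sub, _r) in enumerate(res_keys):
        if sub not in subunits:
            subunits.append(sub)
        residue_segindex[j] = subunits.index(sub)

    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(res_keys),
        n_segments=len(subunits),
        atom_resindex=atom_resindex,
        residue_segindex=residue_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("name", [s.name for s in topology])
    first_site_of_res = {}
    for s in topology:
        first_site_of_res.setdefault((s.subunit, s.resid), s.resname)
    u.add_TopologyAttr("resname", [first_site_of_res[k] for k in res_keys])
    u.add_TopologyAttr("resid", [r for (_s, r) in res_keys])
    chains = [_CHAIN_LETTERS[i % len(_CHAIN_LETTERS)] for i in range(len(subunits))]
    u.add_TopologyAttr("segid", chains)
    u.add_TopologyAttr("chainID", [chains[residue_segindex[atom_resindex[i]]] for i in range(n_atoms)])
    u.load_new(np.asarray(coords_nm, dtype=np.float32) * ANGSTROM_PER_NM, format=MemoryReader)
    return u


def write_ensemble(
    ensemble: TrajectoryEnsemble,
    out_dir: str | Path,
    fmt: str = "pdb",
    stem: str = "traj",
) -> list[Path]:
    """Write one multi-frame file per trajectory plus a JSON topology sidecar.

    PDB files carry coordinates in Å (three decimals, i.e. 1e-3 Å precision);
    XYZ files are written in Å as well for consistency with common viewers.
    """
    import MDAnalysis as mda

    fmt = fmt.lower()
    if fmt not in ("pdb", "xyz"):
        raise FormatError(f"unsupported output format {fmt!r} (use 'pdb' or 'xyz')")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj in ensemble.trajectories:
        u = _universe_from(ensemble.topology, traj.coords)
        path = out_dir / f"{stem}_{traj.trajectory_id}.{fmt}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MDAnalysis warns about absent elements etc.
            with mda.Writer(str(path), n_atoms=ensemble.n_sites, multiframe=True) as w:
                for _ts in u.trajectory:
                    w.write(u.atoms)
        meta = {
            "sites": _topology_to_json(ensemble.topology),
            "frame_interval_ns": traj.frame_interval,
            "t0_ns": float(traj.times[0]) if traj.n_frames else traj.t0,
            "trajectory_id": traj.trajectory_id,
            "model_tag": traj.model_tag,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        paths.append(path)
    return paths


def read_ensemble(
    paths: Sequence[str | Path] | str | Path,
    topology_spec: Sequence[Site] | dict | None = None,
    *,
    frame_interval: float = 0.1,
    t0: float = 0.0,
    model_tag: str = "",
) -> TrajectoryEnsemble:
    """Read multi-model PDB / XYZ files into one ensemble (coordinates → nm).

    ``topology_spec`` may be a full list of :class:`Site` records
    (authoritative, required for label-less formats like XYZ without a
    sidecar) or a mapping from chain identifier to subunit label.  When it is
    None, a JSON sidecar written by :func:`write_ensemble` is used if
    present; otherwise labels are derived from the file (chain identifier as
    the subunit label).
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    topology: list[Site] | None = list(topology_spec) if _is_site_list(topology_spec) else None
    chain_map = topology_spec if isinstance(topology_spec, dict) else None
    trajectories: list[Trajectory] = []
    for k, p in enumerate(paths):
        p = Path(p)
        if not p.exists():
            raise FormatError(f"no such trajectory file: {p}")
        suffix = p.suffix.lower()
        if suffix not in (".pdb", ".ent", ".xyz"):
            raise FormatError(f"unknown trajectory format {suffix!r} for {p.name}")
        sidecar = _sidecar_path(p)
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(str(p))
            except Exception as exc:  # pragma: no cover - passthrough detail
                raise StructureError(f"failed to parse {p.name}: {exc}") from exc
            file_topology = _topology_from_universe(u, chain_map)
            coords = np.array(
                [u.atoms.positions.copy() for _ts in u.trajectory], dtype=float
            ) * NM_PER_ANGSTROM
        if topology is None and meta.get("sites"):
            topology = _topology_from_json(meta["sites"])
        if topology is None:
            topology = file_topology
        if coords.shape[1] != len(topology):
            raise StructureError(
                f"{p.name}: {coords.shape[1]} atoms per frame, topology has {len(topology)}"
            )
        trajectories.append(
            Trajectory(
                coords=coords,
                frame_interval=float(meta.get("frame_interval_ns", frame_interval)),
                t0=float(meta.get("t0_ns", t0)),
                trajectory_id=str(meta.get("trajectory_id", p.stem or f"traj{k}")),
                model_tag=str(meta.get("model_tag", model_tag)),
            )
        )
    assert topology is not None
    return TrajectoryEnsemble(topology=topology, trajectories=trajectories)


def _is_site_list(obj) -> bool:
    return (
        obj is not None
        and not isinstance(obj, dict)
        and len(obj) > 0
        and isinstance(obj[0], Site)
    )


def _topology_from_universe(u, chain_map: dict | None) -> list[Site]:
    n = len(u.atoms)
    names = getattr(u.atoms, "names", None)
    resids = getattr(u.atoms, "resids", None)
    resnames = getattr(u.atoms, "resnames", None)
    chains = getattr(u.atoms, "chainIDs", None)
    if chains is None:
        chains = getattr(u.atoms, "segids", None)
    sites = []
    for i in range(n):
        chain = str(chains[i]) if chains is not None else "A"
        subunit = chain_map.get(chain, chain) if chain_map else chain
        sites.append(
            Site(
                name=str(names[i]) if names is not None else f"S{i+1}",
                resid=int(resids[i]) if resids is not None else i + 1,
                resname=str(resnames[i]) if resnames is not None else "UNK",
                subunit=subunit or "A",
            )
        )
    return sites


# ---------------------------------------------------------------------------
# distance extraction, trimming, concatenation
# ---------------------------------------------------------------------------


def extract_distance(
    ensemble: TrajectoryEnsemble, site_a_selector, site_b_selector
) -> list[DistanceSeries]:
    """Per-frame Euclidean distance between two uniquely selected sites.

    Returns one series per trajectory.  Rigid rotations/translations of the
    frames leave the result unchanged (distances are invariant).
    """
    ia = resolve_single_site(ensemble.topology, site_a_selector)
    ib = resolve_single_site(ensemble.topology, site_b_selector)
    label = f"{ensemble.topology[ia].subunit}:{ensemble.topology[ia].name}" \
        f"–{ensemble.topology[ib].subunit}:{ensemble.topology[ib].name}"
    out = []
    for traj in ensemble.trajectories:
        diff = traj.coords[:, ia, :] - traj.coords[:, ib, :]
        values = np.linalg.norm(diff, axis=1)
        out.append(
            DistanceSeries(
                times=traj.times.copy(),
                values=values,
                pair_label=label,
                trajectory_id=traj.trajectory_id,
                t_origin=traj.t_origin,
            )
        )
    return out


def trim_equilibration(obj, t_discard: float):
    """Drop the initial ``t_discard`` ns of every trajectory independently.

    Frames with time < t_origin + t_discard are removed; the origin advances
    by ``t_discard`` so that trimming composes additively.
    """
    if t_discard < 0:
        raise ParameterError("t_discard must be >= 0 ns")
    if isinstance(obj, TrajectoryEnsemble):
        return TrajectoryEnsemble(
            topology=obj.topology,
            trajectories=[trim_equilibration(t, t_discard) for t in obj.trajectories],
        )
    if isinstance(obj, Trajectory):
        cut = obj.t_origin + t_discard
        keep = obj.times >= cut - 1e-12
        if not np.any(keep):
            raise EmptyTrajectoryError(
                f"t_discard={t_discard} ns removes every frame of trajectory "
                f"{obj.trajectory_id!r}"
            )
        return replace(
            obj,
            coords=obj.coords[keep],
            times=obj.times[keep],
            t_origin=cut,
        )
    if isinstance(obj, DistanceSeries):
        cut = obj.t_origin + t_discard
        keep = obj.times >= cut - 1e-12
        if not np.any(keep):
            raise EmptyTrajectoryError(
                f"t_discard={t_discard} ns removes every frame of series "
                f"{obj.trajectory_id!r}"
            )
        return DistanceSeries(
            times=obj.times[keep],
            values=obj.values[keep],
            pair_label=obj.pair_label,
            trajectory_id=obj.trajectory_id,
            boundaries=(),
            t_origin=cut,
        )
    raise ParameterError(f"cannot trim object of type {type(obj).__name__}")


def concatenate(series_list: Sequence[DistanceSeries]) -> DistanceSeries:
    """Append series frame-wise; the output time axis is a bare frame index.

    The concatenation represents pooled sampling of configuration space, not
    a single course of events, so physical times are deliberately replaced by
    an arbitrary reaction-coordinate index; segment boundaries are recorded.
    """
    if not series_list:
        raise ParameterError("cannot concatenate an empty series list")
    labels = {s.pair_label for s in series_list}
    if len(labels) > 1:
        raise LabelError(f"mixed pair labels in concatenation: {sorted(labels)}")
    values = np.concatenate([s.values for s in series_list])
    lengths = [s.n for s in series_list]
    boundaries = tuple(np.cumsum(lengths)[:-1].tolist())
    return DistanceSeries(
        times=np.arange(values.shape[0], dtype=float),
        values=values,
        pair_label=series_list[0].pair_label,
        trajectory_id="+".join(s.trajectory_id for s in series_list),
        boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# sampling-plan accounting
# ---------------------------------------------------------------------------


def sampling_plan_summary(plan) -> pd.DataFrame:
    """Exact scheduled/discarded/analyzed time accounting per sampling block.

    ``plan`` rows give (label, count, duration_ns, discard_ns); a pandas
    DataFrame with those columns is also accepted.  Arithmetic is exact
    (Fraction) and reported in ns plus µs convenience columns, with a TOTAL
    row appended.  Blocks whose discard equals their duration contribute zero
    analyzed time (e.g. runs used only for equilibration).
    """
    if isinstance(plan, pd.DataFrame):
        rows = plan.to_dict("records")
    else:
        rows = [
            r if isinstance(r, dict) else dict(zip(("label", "count", "duration_ns", "discard_ns"), r))
            for r in plan
        ]
    records = []
    for r in rows:
        count = int(r["count"])
        duration = Fraction(r["duration_ns"]).limit_denominator(10**9)
        discard = Fraction(r.get("discard_ns", 0)).limit_denominator(10**9)
        if count < 0 or duration < 0 or discard < 0:
            raise ParameterError(f"negative entries in sampling-plan row {r!r}")
        if discard > duration:
            raise ParameterError(f"discard exceeds duration in row {r!r}")
        scheduled = count * duration
        discarded = count * discard
        records.append(
            {
                "label": str(r.get("label", "block")),
                "count": count,
                "duration_ns": duration,
                "discard_ns": discard,
                "scheduled_ns": scheduled,
                "discarded_ns": discarded,
                "analyzed_ns": scheduled - discarded,
            }
        )
    total = {
        "label": "TOTAL",
        "count": sum(r["count"] for r in records),
        "duration_ns": Fraction(0),
        "discard_ns": Fraction(0),
        "scheduled_ns": sum((r["scheduled_ns"] for r in records), Fraction(0)),
        "discarded_ns": sum((r["discarded_ns"] for r in records), Fraction(0)),
        "analyzed_ns": sum((r["analyzed_ns"] for r in records), Fraction(0)),
    }
    records.append(total)
    df = pd.DataFrame(records)
    for col in ("scheduled_ns", "discarded_ns", "analyzed_ns"):
        df[col.replace("_ns", "_us")] = [float(v) / 1000.0 for v in df[col]]
    return df
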