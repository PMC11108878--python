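"""End-to-end orchestration: simulate/read → extract → trim → analyze → report.

:func:`run_pipeline` takes a :class:`PipelineConfig` (usually loaded from
YAML), runs the requested stages, and writes a deterministic bundle of
TSV/JSON/GraphML outputs plus a run manifest (config hash, seed, package
version).  Rerunning with the same config and seed yields bit-identical
numeric outputs and manifests.  :func:`render_report` regenerates figures
from the exported tables alone, without recomputation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distributions as dist_mod
from . import flexibility as flex_mod
from . import network as net_mod
from . import occupancy as occ_mod
from .exceptions import ConfigError, CorrShuttleError
from .synthetic import (
    PlantedNetworkParams,
    SwitchingModelParams,
    embed_distances_as_trajectory,
    simulate_ou,
    simulate_switching_distances,
)
from .trajectory import (
    DistanceSeries,
    concatenate,
    extract_distance,
    read_ensemble,
    sampling_plan_summary,
    trim_equilibration,
    write_ensemble,
)

ALL_STAGES = ("simulate", "extract", "occupancy", "distributions", "flexibility", "network")

_FLOAT_FMT = "%.9g"


def default_config(seed: int = 0, output_dir: str = "corrshuttle_out") -> dict:
    """Synthetic-run defaults: six independent switching trajectories,
    equilibration trimming, full (C, d) sweep and the planted-ring network."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "synthetic": {
            "n_trajectories": 6,
            "switching": {
                "mean_a": [3.2, 2.5],
                "mean_b": [2.7, 2.8],
                "sigma": 0.08,
                "theta": 1.0,
                "k_ab": 0.05,
                "k_ba": 0.05,
                "dt": 0.1,
                "n_frames": 20000,
                "coupled": True,
            },
            "one_x": {"mu": 2.6, "sigma": 0.15, "theta": 1.0},
            "network": {
                "n_residues": 24,
                "planted_path": list(range(13)),
                "on_path_correlation": 0.9,
                "off_path_correlation": 0.1,
                "chain_geometry": 0.4,
                "n_frames": 20000,
                "displacement_std": 0.05,
                "mobile_scale": 2.0,
                "mobile_residues": list(range(12, 24)),
                "subunit_split": 12,
            },
            "write_trajectory": False,
        },
        "trim_ns": 200.0,
        "occupancy": {
            "c_min": 0.67, "c_max": 1.0, "c_step": 0.01,
            "d_min": 1.5, "d_max": 4.5, "d_step": 0.01,
            "highlight_c": [0.8, 0.9, 1.0],
        },
        "distributions": {"bin_width": 0.05, "bandwidth": "auto", "min_prominence": 0.05},
        "flexibility": {
            "selections": {"docked": "RINGA:1-12", "distant": "RINGB:1-12"},
            "reference": "first",
        },
        "network": {
            "contact_cutoff": 0.5,
            "occupancy": 0.75,
            "source": "RINGA:1",
            "sink": "RINGB:1",
            "hop_cutoff": 0.8,
        },
    }


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (exactly one input source)."""

    seed: int = 0
    output_dir: str = "corrshuttle_out"
    inputs: dict | None = None
    synthetic: dict | None = None
    trim_ns: float = 200.0
    occupancy: dict = field(default_factory=dict)
    distributions: dict = field(default_factory=dict)
    flexibility: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of 'inputs' (trajectory files) or 'synthetic' "
                "(generator parameters) must be configured"
            )
        if self.trim_ns < 0:
            raise ConfigError("trim_ns must be >= 0")
        if self.inputs is not None and not self.inputs.get("paths"):
            raise ConfigError("'inputs' requires a non-empty 'paths' list")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        if not isinstance(cfg, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(cfg)

    def to_canonical_json(self) -> str:
        def enc(o):
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o).__name__)
        payload = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "inputs": self.inputs,
            "synthetic": self.synthetic,
            "trim_ns": self.trim_ns,
            "occupancy": self.occupancy,
            "distributions": self.distributions,
            "flexibility": self.flexibility,
            "network": self.network,
        }
        return json.dumps(payload, sort_keys=True, default=enc)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()


def _derived_seed(base: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(base), int(stream)]).generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def _acquire_series(config: PipelineConfig, out: Path, record):
    """Produce the trimmed, concatenated Fe–Fe and Fe–Mg series."""
    if config.synthetic is not None:
        syn = config.synthetic
        n_traj = int(syn.get("n_trajectories", 6))
        sw = dict(syn.get("switching", {}))
        sw.pop("seed", None)
        fe_fe_parts, fe_mg_parts = [], []
        plan_rows = []
        for k in range(n_traj):
            params = SwitchingModelParams(
                **{**sw, "mean_a": tuple(sw.get("mean_a", (3.2, 2.5))),
                   "mean_b": tuple(sw.get("mean_b", (2.7, 2.8)))},
                seed=_derived_seed(config.seed, 100 + k),
            )
            sample = simulate_switching_distances(params)
            # embed as 3-D marker beads and re-extract: the distances the
            # pipeline analyzes always pass through coordinate space
            ens = embed_distances_as_trajectory(sample.fe_fe, sample.fe_mg,
                                                trajectory_id=f"run{k}")
            if k == 0 and syn.get("write_trajectory", False):
                write_ensemble(ens, out / "trajectories", fmt="pdb", stem="markers")
                sample.write_sidecar(out / "trajectories", stem=f"switching_run{k}")
            ens = trim_equilibration(ens, config.trim_ns)
            (fe_fe_k,) = extract_distance(ens, "PscC_docked:FE", "PscC_distant:FE")
            (fe_mg_k,) = extract_distance(ens, "PscC_docked:FE", "PscA:MG")
            fe_fe_parts.append(fe_fe_k)
            fe_mg_parts.append(fe_mg_k)
        duration = sw.get("n_frames", 20000) * sw.get("dt", 0.1)
        plan_rows.append(("classical production", n_traj, duration, config.trim_ns))
        record["sampling_plan"] = sampling_plan_summary(plan_rows)
    else:
        inp = config.inputs
        sel = inp.get("selectors", {})
        fe_fe_parts, fe_mg_parts = [], []
        for path in inp["paths"]:
            ens = read_ensemble(path, topology_spec=None,
                                frame_interval=float(inp.get("frame_interval_ns", 0.1)))
            ens = trim_equilibration(ens, config.trim_ns)
            fe_fe_parts.extend(extract_distance(
                ens, sel.get("fe_docked", "PscC_docked:FE"), sel.get("fe_distant", "PscC_distant:FE")))
            fe_mg_parts.extend(extract_distance(
                ens, sel.get("fe_docked", "PscC_docked:FE"), sel.get("mg", "PscA:MG")))
        durations = [(p.n * np.median(np.diff(p.times)) + config.trim_ns) for p in fe_fe_parts]
        record["sampling_plan"] = sampling_plan_summary(
            [("input trajectories", 1, d, config.trim_ns) for d in durations]
        )
    return concatenate(fe_fe_parts), concatenate(fe_mg_parts)


def _network_ensemble(config: PipelineConfig):
    syn = config.synthetic or {}
    net = dict(syn.get("network", {}))
    if "planted_path" in net:
        net["planted_path"] = tuple(net["planted_path"])
    if "mobile_residues" in net:
        net["mobile_residues"] = tuple(net["mobile_residues"])
    params = PlantedNetworkParams(**net, seed=_derived_seed(config.seed, 500))
    from .synthetic import generate_planted_network_trajectory

    return generate_planted_network_trajectory(params)


def run_pipeline(config: PipelineConfig | dict, stages=None) -> Path:
    """Run the requested stages and write the report bundle.

    Returns the bundle directory.  Stage errors are re-raised annotated with
    the stage name.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record: dict = {}
    manifest_outputs: list[str] = []

    def stage(name):
        return name in stages

    try:
        fe_fe, fe_mg = _acquire_series(config, out, record)
    except CorrShuttleError as exc:
        raise type(exc)(f"[stage simulate/extract] {exc}") from exc

    if stage("extract") or stage("simulate"):
        fe_fe.to_tsv(out / "series_fe_fe.tsv")
        fe_mg.to_tsv(out / "series_fe_mg.tsv")
        _write_tsv(record["sampling_plan"].drop(
            columns=["duration_ns", "discard_ns"]).astype({"count": int}),
            out / "sampling_plan.tsv")
        manifest_outputs += ["series_fe_fe.tsv", "series_fe_mg.tsv", "sampling_plan.tsv"]

    if stage("occupancy"):
        try:
            occ = config.occupancy
            c_list = None
            d_grid = None
            if occ:
                c_list = np.round(np.arange(occ.get("c_min", 0.67), occ.get("c_max", 1.0) + 1e-9,
                                            occ.get("c_step", 0.01)), 6)
                d_grid = np.round(np.arange(occ.get("d_min", 1.5), occ.get("d_max", 4.5) + 1e-9,
                                            occ.get("d_step", 0.01)), 6)
            curves = occ_mod.occupancy_curves(fe_fe, fe_mg, d_grid=d_grid, C_list=c_list)
            _write_tsv(occ_mod.curves_to_frame(curves), out / "occupancy_curves.tsv")
            peaks = occ_mod.table_report(curves)
            _write_tsv(peaks, out / "occupancy_peaks.tsv")
            cloud = occ_mod.project_frames(fe_fe, fe_mg)
            for c in (occ or {}).get("highlight_c", [0.8, 0.9, 1.0]):
                sub = peaks[np.isclose(peaks["C"], c)]
                if len(sub):
                    best = sub.sort_values(["percent", "d_peak_nm"],
                                           ascending=[False, True]).iloc[0]
                    occ_mod.flag_membership(cloud, float(best["C"]), float(best["d_peak_nm"]))
            _write_tsv(cloud, out / "projection.tsv")
            manifest_outputs += ["occupancy_curves.tsv", "occupancy_peaks.tsv", "projection.tsv"]
        except CorrShuttleError as exc:
            raise type(exc)(f"[stage occupancy] {exc}") from exc

    if stage("distributions"):
        try:
            d = config.distributions
            kw = dict(bin_width=d.get("bin_width", 0.05), bandwidth=d.get("bandwidth", "auto"))
            prom = d.get("min_prominence", 0.05)
            modes_out = {}
            for name, series in (("fe_fe", fe_fe), ("fe_mg", fe_mg)):
                summ = dist_mod.summarize(series, **kw)
                hist, kde = summ.to_frames()
                _write_tsv(hist, out / f"hist_{name}.tsv")
                _write_tsv(kde, out / f"kde_{name}.tsv")
                modes = dist_mod.find_modes(summ, min_prominence=prom)
                modes_out[name] = {"locations_nm": list(modes.locations),
                                   "prominences": list(modes.prominences),
                                   "bandwidth_nm": modes.bandwidth}
                manifest_outputs += [f"hist_{name}.tsv", f"kde_{name}.tsv"]
            _write_json(modes_out, out / "modes.json")
            manifest_outputs.append("modes.json")
            if config.synthetic is not None:
                ox = config.synthetic.get("one_x", {})
                one_x = simulate_ou(
                    theta=float(ox.get("theta", 1.0)), mu=float(ox.get("mu", 2.6)),
                    sigma=float(ox.get("sigma", 0.15)),
                    dt=config.synthetic.get("switching", {}).get("dt", 0.1),
                    n=max(fe_mg.n, 2), seed=_derived_seed(config.seed, 900),
                )
                comparison = dist_mod.compare_models(fe_mg, one_x, **kw, min_prominence=prom)
                _write_json(comparison, out / "model_comparison.json")
                manifest_outputs.append("model_comparison.json")
        except CorrShuttleError as exc:
            raise type(exc)(f"[stage distributions] {exc}") from exc

    needs_net_ens = (stage("flexibility") or stage("network")) and config.synthetic is not None
    planted = _network_ensemble(config) if needs_net_ens else None

    if stage("flexibility") and planted is not None:
        try:
            fx = config.flexibility
            sels = fx.get("selections", {"docked": "RINGA:1-12", "distant": "RINGB:1-12"})
            ref = fx.get("reference", "first")
            profiles = {}
            for name, sel in sels.items():
                profiles[name] = flex_mod.flexibility_profile(planted.ensemble, sel, reference=ref)
            rmsd_frames = []
            rmsf_frames = []
            for name, prof in profiles.items():
                df = prof.rmsd.copy()
                df.insert(0, "selection", name)
                rmsd_frames.append(df)
                rmsf_frames.append(pd.DataFrame({
                    "selection": name, "resid": prof.rmsf.index, "rmsf_nm": prof.rmsf.to_numpy()
                }))
            _write_tsv(pd.concat(rmsd_frames, ignore_index=True), out / "flexibility_rmsd.tsv")
            _write_tsv(pd.concat(rmsf_frames, ignore_index=True), out / "flexibility_rmsf.tsv")
            names = list(profiles)
            if len(names) >= 2:
                cmp = flex_mod.flexibility_compare(profiles[names[0]], profiles[names[1]])
                label_map = {profiles[names[0]].selection: names[0],
                             profiles[names[1]].selection: names[1]}
                _write_json(
                    {
                        "median_rmsf_nm": {label_map[k]: v for k, v in cmp["median_rmsf_nm"].items()},
                        "median_rmsd_nm": {label_map[k]: v for k, v in cmp["median_rmsd_nm"].items()},
                        "more_mobile": label_map.get(cmp["more_mobile"], cmp["more_mobile"]),
                    },
                    out / "flexibility_compare.json",
                )
                manifest_outputs.append("flexibility_compare.json")
            manifest_outputs += ["flexibility_rmsd.tsv", "flexibility_rmsf.tsv"]
        except CorrShuttleError as exc:
            raise type(exc)(f"[stage flexibility] {exc}") from exc

    if stage("network") and planted is not None:
        try:
            ncfg = config.network
            corr = net_mod.displacement_correlation(planted.ensemble)
            G = net_mod.build_graph(
                corr, planted.ensemble,
                contact_cutoff=float(ncfg.get("contact_cutoff", 0.5)),
                occupancy=float(ncfg.get("occupancy", 0.75)),
            )
            _write_tsv(net_mod.graph_to_edge_table(G), out / "network_edges.tsv")
            import networkx as nx

            nx.write_graphml(G, out / "network.graphml")
            source = ncfg.get("source", planted.path_labels[0])
            sink = ncfg.get("sink", planted.path_labels[-1])
            path = net_mod.shortest_pathway(G, source, sink)
            _write_tsv(path.to_frame(), out / "pathway.tsv")
            bc = net_mod.betweenness(G)
            _write_tsv(
                pd.DataFrame(sorted(bc.items()), columns=["node", "betweenness"]),
                out / "betweenness.tsv",
            )
            hop = net_mod.aromatic_hop_pathway(
                planted.ensemble, source, sink, hop_cutoff=float(ncfg.get("hop_cutoff", 0.8))
            )
            _write_tsv(hop.to_frame(), out / "aromatic_pathway.tsv")
            manifest_outputs += ["network_edges.tsv", "network.graphml", "pathway.tsv",
                                 "betweenness.tsv", "aromatic_pathway.tsv"]
        except CorrShuttleError as exc:
            raise type(exc)(f"[stage network] {exc}") from exc

    from . import __version__

    manifest = {
        "package": "corrshuttle",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "stages": sorted(stages),
        "n_frames_analyzed": int(fe_fe.n),
        "outputs": sorted(set(manifest_outputs)),
    }
    _write_json(manifest, out / "manifest.json")
    return out


# ---------------------------------------------------------------------------
# figures (from exported tables only)
# ---------------------------------------------------------------------------


def render_report(bundle_dir: str | Path, out_dir: str | Path | None = None):
    """Regenerate the figure panel set from the bundle's TSV tables.

    Returns (figure paths, warnings).  Missing stage outputs are reported as
    warnings and skipped; an empty bundle yields an empty report.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bundle = Path(bundle_dir)
    out = Path(out_dir) if out_dir else bundle / "figures"
    out.mkdir(parents=True, exist_ok=True)
    figures: list[Path] = []
    warnings_: list[str] = []

    def have(*names):
        missing = [n for n in names if not (bundle / n).exists()]
        if missing:
            warnings_.append(f"missing stage output(s): {', '.join(missing)}")
            return False
        return True

    def save(fig, name):
        path = out / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        figures.append(path)

    if have("series_fe_fe.tsv", "series_fe_mg.tsv"):
        s1 = pd.read_csv(bundle / "series_fe_fe.tsv", sep="\t")
        s2 = pd.read_csv(bundle / "series_fe_mg.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(9, 3.2))
        ax.plot(s1["distance_nm"], lw=0.4, color="tab:red", label="Fe–Fe")
        ax.plot(s2["distance_nm"], lw=0.4, color="tab:green", label="Fe–Mg(P840)")
        for b in s1.index[s1["segment_index"].diff() > 0]:
            ax.axvline(b, color="0.7", lw=0.6)
        ax.set_xlabel("concatenated frame (arbitrary reaction coordinate)")
        ax.set_ylabel("distance (nm)")
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        save(fig, "coevolution.png")

    if have("occupancy_curves.tsv"):
        df = pd.read_csv(bundle / "occupancy_curves.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        colors = {0.8: "tab:red", 0.9: "tab:blue", 1.0: "tab:green"}
        for c, grp in df.groupby("C"):
            col = colors.get(round(float(c), 2))
            ax.plot(grp["d_nm"], 100 * grp["fraction"], lw=1.4 if col else 0.5,
                    color=col or "0.75", label=f"C={c:.2f}" if col else None)
        ax.set_xlabel("d (nm)")
        ax.set_ylabel("% of sampled frames")
        ax.legend(fontsize=8)
        fig.tight_layout()
        save(fig, "occupancy_curves.png")

    if have("projection.tsv"):
        df = pd.read_csv(bundle / "projection.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(4.8, 4.8))
        member_cols = [c for c in df.columns if c.startswith("member_")]
        ax.scatter(df["d1_nm"], df["d2_nm"], s=2, color="0.8", lw=0)
        for col, color in zip(member_cols, ("tab:red", "tab:blue", "tab:green")):
            sub = df[df[col]]
            ax.scatter(sub["d1_nm"], sub["d2_nm"], s=2, color=color, lw=0, label=col)
        ax.set_xlabel("Fe–Fe distance (nm)")
        ax.set_ylabel("Fe–Mg(P840) distance (nm)")
        if member_cols:
            ax.legend(fontsize=7, markerscale=3)
        fig.tight_layout()
        save(fig, "projection.png")

    if have("series_fe_fe.tsv", "series_fe_mg.tsv"):
        s1 = pd.read_csv(bundle / "series_fe_fe.tsv", sep="\t")
        s2 = pd.read_csv(bundle / "series_fe_mg.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(4.5, 4))
        parts = ax.violinplot([s1["distance_nm"], s2["distance_nm"]], showmedians=True)
        for body, col in zip(parts["bodies"], ("tab:red", "tab:green")):
            body.set_facecolor(col)
        ax.set_xticks([1, 2], ["Fe–Fe", "Fe–Mg(P840)"])
        ax.set_ylabel("distance (nm)")
        fig.tight_layout()
        save(fig, "distance_violins.png")

    if have("flexibility_rmsd.tsv", "flexibility_rmsf.tsv"):
        rmsd = pd.read_csv(bundle / "flexibility_rmsd.tsv", sep="\t")
        rmsf = pd.read_csv(bundle / "flexibility_rmsf.tsv", sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.6))
        for ax, df, col in ((axes[0], rmsd, "rmsd_nm"), (axes[1], rmsf, "rmsf_nm")):
            groups = [grp[col].to_numpy() for _n, grp in df.groupby("selection")]
            names = [n for n, _g in df.groupby("selection")]
            ax.violinplot(groups, showmedians=True)
            ax.set_xticks(range(1, len(names) + 1), names)
            ax.set_ylabel(f"{col.split('_')[0].upper()} (nm)")
        fig.tight_layout()
        save(fig, "flexibility_violins.png")

    if have("network_edges.tsv", "pathway.tsv"):
        import networkx as nx

        edges = pd.read_csv(bundle / "network_edges.tsv", sep="\t")
        pathway = pd.read_csv(bundle / "pathway.tsv", sep="\t")
        G = nx.Graph()
        for _i, r in edges.iterrows():
            G.add_edge(r["node_i"], r["node_j"], weight=float(r["weight"]))
        pos = nx.circular_layout(sorted(G.nodes()))
        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        nx.draw_networkx(G, pos=pos, ax=ax, node_size=160, font_size=6,
                         node_color="0.85", edge_color="0.7")
        path_nodes = pathway["node"].tolist()
        path_edges = list(zip(path_nodes[:-1], path_nodes[1:]))
        nx.draw_networkx_edges(G, pos=pos, edgelist=path_edges, ax=ax,
                               edge_color="tab:red", width=2.2)
        ax.set_axis_off()
        fig.tight_layout()
        save(fig, "pathway.png")

    return figures, warnings_
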