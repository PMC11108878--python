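"""Dynamical-network analysis of residue-residue correlated motion.

A residue-level weighted graph is built from the normalized covariance of
bead displacements, restricted to persistent contacts, with edge weight
w_ij = −log|C_ij| (the convention of the dynamical-network literature: path
weight then corresponds to a product of correlation magnitudes).  Minimum-
weight paths between named endpoints — e.g. distant cytochrome heme →
docked cytochrome heme → special pair — proxy allosteric communication
routes, and weighted betweenness identifies hub residues.

A simplified geometric aromatic-hop pathway (centroid graph over Trp / Tyr /
Phe rings and cofactors, edges below a hop cutoff, weight = distance) is
provided as a declared stand-in for electronic-coupling pathway methods,
which this package does not implement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import NoPathError, ParameterError
from .trajectory import TrajectoryEnsemble, resolve_selection

DEFAULT_CONTACT_CUTOFF = 0.5   # nm between representative beads
DEFAULT_CONTACT_OCCUPANCY = 0.75  # fraction of frames the contact must persist


@dataclass
class CorrelationResult:
    """Residue-displacement correlation matrix with node labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    zero_variance: tuple[str, ...] = ()


@dataclass
class PathwayResult:
    """An ordered minimum-weight path between two endpoints."""

    nodes: tuple[str, ...]
    edge_weights: tuple[float, ...]
    total_weight: float
    source: str
    sink: str

    def to_frame(self) -> pd.DataFrame:
        steps = [math.nan] + list(self.edge_weights)
        return pd.DataFrame({"order": np.arange(len(self.nodes)), "node": self.nodes,
                             "edge_weight": steps})


def _node_positions(ensemble: TrajectoryEnsemble, selection=None):
    """Representative bead per residue: pooled coords + 'subunit:resid' labels.

    If a residue has several selected sites its centroid is used.
    """
    idx = (
        np.arange(ensemble.n_sites)
        if selection is None
        else resolve_selection(ensemble.topology, selection)
    )
    keys: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[int]] = {}
    for i in idx:
        s = ensemble.topology[i]
        key = (s.subunit, s.resid)
        if key not in groups:
            keys.append(key)
            groups[key] = []
        groups[key].append(int(i))
    frames = ensemble.pooled_coords()
    pos = np.stack(
        [frames[:, groups[k], :].mean(axis=1) for k in keys], axis=1
    )  # (n_frames, n_nodes, 3)
    labels = tuple(f"{sub}:{resid}" for sub, resid in keys)
    return labels, pos


def displacement_correlation(
    ensemble: TrajectoryEnsemble, selection=None
) -> CorrelationResult:
    """Normalized dot-product covariance of bead displacements.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), with Δr the deviation
    from the mean position over pooled frames.  Rigid-body motion is assumed
    to have been removed beforehand (superpose the ensemble first when the
    input has global drift).  Zero-variance nodes are flagged and their
    off-diagonal correlations set to 0.
    """
    labels, pos = _node_positions(ensemble, selection)
    if pos.shape[0] < 2:
        raise ParameterError("need >= 2 frames for displacement correlations")
    delta = pos - pos.mean(axis=0)
    cov = np.einsum("fia,fja->ij", delta, delta) / delta.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-12 * float(var.max(initial=0.0))
    denom = np.sqrt(np.where(zero, 1.0, var))
    C = cov / np.outer(denom, denom)
    if zero.any():
        C[zero, :] = 0.0
        C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    np.clip(C, -1.0, 1.0, out=C)
    return CorrelationResult(
        labels=labels,
        matrix=C,
        zero_variance=tuple(l for l, z in zip(labels, zero) if z),
    )


def contact_occupancy_matrix(
    ensemble: TrajectoryEnsemble, selection=None, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    chunk: int = 2000,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Fraction of pooled frames in which each bead pair is within the cutoff."""
    if contact_cutoff <= 0:
        raise ParameterError("contact_cutoff must be > 0 nm")
    labels, pos = _node_positions(ensemble, selection)
    n_frames, n_nodes = pos.shape[0], pos.shape[1]
    counts = np.zeros((n_nodes, n_nodes))
    for lo in range(0, n_frames, chunk):
        block = pos[lo : lo + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        within = np.linalg.norm(diff, axis=3) < contact_cutoff
        counts += within.sum(axis=0)
    return labels, counts / n_frames


def build_graph(
    correlations: CorrelationResult,
    ensemble: TrajectoryEnsemble,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    occupancy: float = DEFAULT_CONTACT_OCCUPANCY,
    selection=None,
) -> nx.Graph:
    """Contact-filtered correlation graph with edge weight −log|C_ij|.

    An edge (i, j) exists iff the representative beads are within
    ``contact_cutoff`` in at least ``occupancy`` of the pooled frames and
    |C_ij| > 0.  |C_ij| = 1 gives weight 0; |C_ij| = e⁻¹ gives weight 1.
    """
    if not (0 < occupancy <= 1):
        raise ParameterError("occupancy must be in (0, 1]")
    labels, contact = contact_occupancy_matrix(ensemble, selection, contact_cutoff)
    if labels != correlations.labels:
        raise ParameterError("correlation matrix does not match the node set")
    C = correlations.matrix
    G = nx.Graph()
    for k, lab in enumerate(labels):
        sub, resid = lab.rsplit(":", 1)
        G.add_node(lab, subunit=sub, resid=int(resid))
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if contact[i, j] < occupancy:
                continue
            c = abs(C[i, j])
            if c <= 0.0:
                continue
            G.add_edge(
                labels[i],
                labels[j],
                weight=float(-np.log(min(c, 1.0))),
                correlation=float(C[i, j]),
                contact_occupancy=float(contact[i, j]),
            )
    return G


def _lexicographic_shortest_path(G: nx.Graph, source: str, sink: str) -> list[str]:
    """Deterministic minimum-weight path: lexicographically smallest node at ties."""
    dist_s = nx.single_source_dijkstra_path_length(G, source, weight="weight")
    if sink not in dist_s:
        comp_s = nx.node_connected_component(G, source)
        comp_t = nx.node_connected_component(G, sink) if sink in G else set()
        raise NoPathError(
            f"{source!r} and {sink!r} are disconnected "
            f"(components of size {len(comp_s)} and {len(comp_t)})"
        )
    dist_t = nx.single_source_dijkstra_path_length(G, sink, weight="weight")
    total = dist_s[sink]
    path = [source]
    u = source
    scale = max(total, 1.0)
    while u != sink:
        best = None
        for v in G[u]:
            w = G[u][v]["weight"]
            if v in dist_t and abs(dist_s[u] + w + dist_t[v] - total) <= 1e-9 * scale + 1e-12:
                if best is None or str(v) < str(best):
                    best = v
        if best is None:  # numerical corner: fall back to networkx's own path
            return nx.dijkstra_path(G, source, sink, weight="weight")
        path.append(best)
        u = best
    return path


def shortest_pathway(G: nx.Graph, source: str, sink: str) -> PathwayResult:
    """Minimum-total-weight pathway between two labeled residues/cofactors."""
    for node in (source, sink):
        if node not in G:
            raise NoPathError(f"endpoint {node!r} is not a node of the graph")
    nodes = _lexicographic_shortest_path(G, source, sink)
    weights = tuple(float(G[a][b]["weight"]) for a, b in zip(nodes[:-1], nodes[1:]))
    return PathwayResult(
        nodes=tuple(nodes),
        edge_weights=weights,
        total_weight=float(sum(weights)),
        source=source,
        sink=sink,
    )


def betweenness(G: nx.Graph) -> dict[str, float]:
    """Normalized weighted shortest-path betweenness centrality per node."""
    if G.number_of_nodes() == 0:
        raise ParameterError("graph is empty")
    return nx.betweenness_centrality(G, weight="weight", normalized=True)


def graph_to_edge_table(G: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "node_i": a,
            "node_j": b,
            "correlation": data.get("correlation", math.nan),
            "weight": data["weight"],
            "contact_occupancy": data.get("contact_occupancy", math.nan),
        }
        for a, b, data in sorted(G.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["node_i", "node_j", "correlation", "weight", "contact_occupancy"])


AROMATIC_RESNAMES = ("TRP", "TYR", "PHE")


def aromatic_hop_pathway(
    ensemble: TrajectoryEnsemble,
    source,
    sink,
    hop_cutoff: float = 0.8,
    frame: tuple[int, int] = (0, 0),
    aromatic_resnames=AROMATIC_RESNAMES,
) -> PathwayResult:
    """Geometric hop pathway over aromatic residues and cofactor endpoints.

    Nodes are the per-residue centroids of aromatic residues plus the
    resolved source/sink sites in one structure frame
    (``frame = (trajectory index, frame index)``); edges connect nodes
    closer than ``hop_cutoff`` (nm) with weight equal to the centroid
    distance.  This is a purely geometric surrogate for an electron-hop
    pathway; no electronic couplings are computed.
    """
    if hop_cutoff <= 0:
        raise ParameterError("hop_cutoff must be > 0 nm")
    ti, fi = frame
    coords = ensemble.trajectories[ti].coords[fi]

    nodes: list[tuple[str, np.ndarray]] = []
    seen: dict[tuple[str, int], list[int]] = {}
    for i, s in enumerate(ensemble.topology):
        if s.resname in aromatic_resnames:
            seen.setdefault((s.subunit, s.resid), []).append(i)
    for (sub, resid), idx in seen.items():
        nodes.append((f"{sub}:{resid}", coords[idx].mean(axis=0)))

    endpoints = []
    for sel in (source, sink):
        idx = resolve_selection(ensemble.topology, sel)
        site = ensemble.topology[int(idx[0])]
        label = f"{site.subunit}:{site.resid}"
        if label not in [lab for lab, _p in nodes]:
            nodes.append((label, coords[idx].mean(axis=0)))
        endpoints.append(label)

    G = nx.Graph()
    for lab, _p in nodes:
        G.add_node(lab)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            dist = float(np.linalg.norm(nodes[a][1] - nodes[b][1]))
            if dist < hop_cutoff:
                G.add_edge(nodes[a][0], nodes[b][0], weight=dist)
    try:
        return shortest_pathway(G, endpoints[0], endpoints[1])
    except NoPathError as exc:
        raise NoPathError(f"{exc}; consider a larger hop_cutoff than {hop_cutoff} nm") from exc
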