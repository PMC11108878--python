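# corrshuttle

Trajectory statistics for the correlated "shuttle" motion of the two PscC
cytochrome domains around the P840 special pair of the green-sulfur-bacterial
(type-I) photosynthetic reaction centre.

## The problem

The reaction centre core (the PscA homodimer) is reduced by two
membrane-anchored cytochrome subunits (PscC, cyt *c_z*), each carrying a
heme-containing soluble domain.  Molecular-dynamics sampling of the
PscA–2×PscC complex suggests the two soluble domains do not act
independently: when they approach each other, the "docked" domain backs away
from the special pair, and when the docked domain sits close to P840 the
"distant" domain moves away — an anticorrelated alternation compatible with
electron transfer *in series* (distant heme → docked heme → P840⁺).

`corrshuttle` packages the analyses needed to quantify that picture from
multi-frame coordinate trajectories:

* **Occupancy statistic** — the fraction of frames in mutually-exclusive
  small/large configurations of the two marker distances.  With
  `D₁ = d(Fe_docked, Fe_distant)` and `D₂ = d(Fe_docked, Mg_P840)`, the
  statistic at threshold `d` and contraction factor `C ∈ (0, 1]` is

  ```
  f(C, d) = |{t : (D₁(t) < C·d ∧ D₂(t) > d) ∨ (D₁(t) > d ∧ D₂(t) < C·d)}| / n_frames
  ```

  swept over a `d` grid for a family of `C` values, with peak detection and a
  per-peak summary table, plus the two-vector frame projection with per-(C,d)
  membership flags.
* **Distance distributions** — histogram + Gaussian-KDE summaries (the
  numeric content of a violin plot), prominence-thresholded mode detection,
  and a two-sample comparison (mean/mode shift, Kolmogorov–Smirnov statistic,
  KDE overlap) of the docked-domain distance between the two-copy and
  one-copy models.
* **Flexibility** — Kabsch superposition, per-frame RMSD and per-residue RMSF
  (iterative mean-structure fit) for named selections such as the
  transmembrane helices (residues 1–100) of each cytochrome copy.
* **Correlation network** — residue-displacement correlation matrix,
  contact-filtered graph with edge weight `−log|C_ij|`, minimum-weight
  (Dijkstra) pathways between named endpoints, weighted betweenness, and a
  geometric aromatic-hop pathway surrogate (Trp/Tyr/Phe centroids).
* **Synthetic generators with ground truth** — a two-state Markov-switching
  pair of distance traces with exact-discretization Ornstein–Uhlenbeck
  fluctuations, an embedding of distance pairs as 3-D marker-bead
  trajectories, and a bead-ring trajectory with a planted correlation
  pathway.  Every downstream stage is tested against the closed forms or
  brute-force oracles these generators admit.
* **Pipeline + CLI** — `corrshuttle all --config cfg.yaml` runs
  simulate/read → trim → occupancy/distributions/flexibility/network and
  writes a deterministic bundle of TSV/JSON/GraphML outputs, a manifest with
  a config hash, and figures rendered from the tables alone.

Trajectories are exchanged as multi-model PDB or XYZ (read/written through
MDAnalysis, Å on disk); all internal units are nm and ns.

## Worked example

```python
from corrshuttle import (SwitchingModelParams, simulate_switching_distances,
                         occupancy_curves, table_report, summarize, find_modes)

params = SwitchingModelParams(n_frames=50_000, seed=7)   # coupled two-state shuttle
sample = simulate_switching_distances(params)
curves = occupancy_curves(sample.fe_fe, sample.fe_mg)    # C in 0.67..1.00, d in 1.5..4.5 nm
print(table_report(curves, C_subset=[0.8, 0.9, 1.0]).to_string(index=False))
modes = find_modes(summarize(sample.fe_mg.values, bandwidth=0.03))
print("Fe–Mg modes (nm):", [round(x, 3) for x in modes.locations])
```

prints

```
  C  d_peak_nm  low_threshold_nm  percent
0.8       3.16             2.528   22.036
0.9       3.00             2.700   52.382
1.0       2.75             2.750   81.324
Fe–Mg modes (nm): [2.507, 2.797]
```

Read: at `C = 1`, for 81% of the frames the two domain–domain/domain–pair
distances sit on opposite sides of 2.75 nm — the mutually-exclusive
alternation the generator planted (its two states put the Fe–Fe distance at
3.2 vs 2.7 nm while the Fe–Mg distance flips 2.5 vs 2.8 nm, which is also
where the detected Fe–Mg modes land).  Tightening `C` demands a deeper
contraction (`D < C·d`) and the occupancy drops accordingly.  On an
*uncoupled* control (`coupled=False`, symmetric rates) the same statistic
settles at the analytic null `2·½·½ = 50 %`.

The same sweep, distribution, flexibility and network stages run end-to-end
from a config file:

```sh
corrshuttle all --config examples/synthetic.yaml   # or rely on built-in defaults
```

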