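# Methods

This note documents the models, estimators and numerical choices behind
`corrshuttle`, and what its synthetic test bed does and does not establish
about real trajectories.

## System and units

The package analyses multi-frame bead/atom trajectories of a photosynthetic
reaction-centre complex: the PscA core homodimer with one or two PscC
cytochrome copies, whose soluble heme domains shuttle between the P840
special pair and each other.  Marker sites are the heme Fe of the docked and
distant PscC domains and the Mg of the P840 bacteriochlorophyll.  All
coordinates and distances are held in nm and all times in ns; PDB files on
disk carry Å as the format requires (three decimals, so file round trips are
exact to 1e-3 Å).  Residue indices are 1-based.  Subunit labels longer than
a PDB chain identifier are carried in a JSON sidecar next to each trajectory
file; reading a bare PDB falls back to chain identifiers.

## Trimming and sampling accounting

Each trajectory independently discards its initial `t_discard` ns as
extended equilibration.  The trim origin advances by exactly `t_discard`
(it does not snap to the first retained frame), which makes trimming compose
additively: trim(t₁) then trim(t₂) equals trim(t₁+t₂) for any frame
interval.  Sampling-plan accounting is exact rational arithmetic over rows
of (count, duration, discard); blocks used purely for equilibration carry
discard = duration and contribute zero analyzed time.  Concatenated distance
series deliberately replace physical time with a bare frame index — pooled
trajectories are a sample of configuration space, not a single course of
events — while recording segment boundaries so autocorrelation-aware
consumers can avoid cross-boundary frame pairs.  All frame-wise statistics
weight frames equally.

## The mutual-exclusion occupancy statistic

For frame-aligned series D₁ (domain–domain) and D₂ (domain–special-pair),

f(C, d) = (1/n) · |{t : (D₁ₜ < C·d ∧ D₂ₜ > d) ∨ (D₁ₜ > d ∧ D₂ₜ < C·d)}|.

Inequalities are strict; a frame lying exactly on a threshold counts for
neither branch (measure-zero under continuous noise).  Defaults sweep
C ∈ {0.67, …, 1.00} in steps of 0.01 and d ∈ [1.5, 4.5] nm in steps of
0.01 nm — fine enough to resolve peak positions quoted at 0.1 nm
granularity with margin.  Both branch sets grow with C by set inclusion, so
f is non-decreasing in C at fixed d, and f vanishes as d → 0⁺ or d → ∞ for
bounded positive series; both properties are asserted in the tests, along
with exact agreement with a naive per-frame loop.  Peaks are interior local
maxima with prominence ≥ 0.02 on the fraction scale (two percentage points,
below the coarsest differences such tables report); plateaus resolve to
their left edge and ties sort toward smaller d.  The statistic is
descriptive; no multiple-testing machinery is attached.

Analytic calibration: a coupled two-state process with well-separated state
means and vanishing noise gives f → 1 at C = 1 for any d strictly between
the two regimes; two independent symmetric-rate processes give
f = 2·(1/2)·(1/2) = 1/2 at the same thresholds.  Both are verified at
n = 10⁵ frames within three autocorrelation-corrected Monte-Carlo standard
errors (see below).

## Distribution summaries and modes

Distance distributions are summarized as a histogram (default bin width
0.05 nm) plus a Gaussian KDE evaluated on a 512-point grid padded four
bandwidths past the sample range (so the density integrates to 1 within
1e-3 even for degenerate samples).  "auto" bandwidth is Silverman's rule; a
fixed kernel std in nm can be given instead.  Modes are KDE local maxima
with prominence at least `min_prominence` (default 0.05) of the global
density maximum — this is the package's operational proxy for "values of
statistical significance" in a violin plot; the mode count itself is not
significance-tested.  Planted Gaussian mixtures at 2.5/2.8 nm and at
2.7/2.9/3.2 nm are recovered within 0.05 nm at n = 10⁵ with a 0.03 nm
kernel.  The two-model comparison reports the mean difference, primary-mode
difference (signed, second minus first), the two-sample Kolmogorov–Smirnov
statistic and the KDE overlap coefficient ∫min(f, g).

## Superposition, RMSD, RMSF

The rigid-body least-squares fit is the Kabsch solution via SVD of the 3×3
cross-covariance, with the determinant guard restricting to proper
rotations.  It is implemented vectorised over whole frame stacks (one
batched SVD), which is why the package does not call a per-frame library
aligner; correctness is cross-checked in the tests against an independent
Euler-angle grid search with Nelder-Mead refinement (agreement ≤ 1e-4 nm on
4-point fixtures) and against the zero-RMSD invariant under arbitrary rigid
motions (≤ 1e-10 nm).  Fits require ≥ 3 non-collinear sites.

Per-frame RMSD fits each frame onto a reference over the measured selection
(default reference: the first analyzed frame; an iterative mean structure is
selectable).  Per-residue RMSF uses the standard iterative procedure — refit
all pooled frames to the running mean structure until the mean moves less
than 1e-6 nm — then RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩).  The fit selection and
the measured selection are independent: the closed-form check (a single
isotropically jittered bead has RMSF = σ√3) pins the fit on the static
beads, because a fit that includes the jittered bead necessarily absorbs
part of its fluctuation (≈ 10 % at 16 beads).  Whether RMSD/RMSF for a
domain should be computed after fitting on that domain's own helices or on
the whole complex is genuinely open; own-selection fitting is the default
and cross-fitting is a parameter.

## Correlation network

Node i is a residue's representative bead (centroid if several sites).
C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over pooled frames, Δr being
the deviation from the mean position; rigid-body motion must be removed
beforehand (the generators used here add none).  Zero-variance nodes are
flagged and decoupled.  Edges exist between beads within 0.5 nm in at least
75 % of frames (both configurable), weighted w_ij = −log|C_ij| so that path
weight corresponds to a product of correlation magnitudes.  Pathways are
minimum-weight Dijkstra paths; among co-optimal paths the lexicographically
smallest node sequence is chosen (deterministic tie-break), verified against
exhaustive simple-path enumeration on ≤ 8-node fixtures, as is the weighted
betweenness.  The aromatic-hop pathway is a purely geometric surrogate —
centroids of Trp/Tyr/Phe rings plus cofactor endpoints, edges below a hop
cutoff (default 0.8 nm), weight = distance; it computes no electronic
couplings and makes no rate claims.

## Synthetic generators (the test bed)

**Switching distances.**  A hidden two-state chain selects per frame between
state A (Fe–Fe 3.2 nm, Fe–Mg 2.5 nm) and state B (Fe–Fe 2.7 nm, Fe–Mg
2.8 nm) — means chosen to land in the distance regimes the real complex
samples, so the synthetic defaults inhabit the same part of configuration
space (Fe–Mg modes near 2.5/2.8 nm; Fe–Fe values within 2.7–3.2 nm).  The
chain is sampled with the exact two-state transition matrix exp(Q·dt)
(p(A→B) = π_B·(1 − e^{−(k_AB+k_BA)·dt})), which keeps the discretized
chain's stationary occupancy exactly k_BA/(k_AB+k_BA) at any frame
interval — a first-order 1 − e^{−k·dt} rule would bias it (0.731 instead of
0.75 at k = 1, 3 ns⁻¹ and dt = 0.1 ns).  Zero-mean OU fluctuations with the
exact discrete update x' = μ + (x−μ)e^{−θdt} + σ√(1−e^{−2θdt})·Z are
superimposed (defaults σ = 0.08 nm, θ = 1 ns⁻¹ — sub-nm fluctuations that
keep the two regimes distinguishable; no quantitative amplitude is published
for the real system, so these are regime-matching choices, not fits), and
values are clamped at 0.1 nm for physical positivity.  Transition rates
default to k_AB = k_BA = 0.05 ns⁻¹ (mean dwell 20 ns).  With
`coupled=False` each series gets an independent chain — the null model.
Hidden states are returned and persisted so occupancy statistics can be
checked against exact ground truth.

**Embedding.**  A distance pair embeds as three collinear beads (Mg at the
origin, docked Fe at the Fe–Mg distance on +x, distant Fe beyond it at the
Fe–Fe distance), so coordinate-level extraction reproduces the input series
to floating point; the pipeline always routes synthetic distances through
this embedding and back, exercising the extraction path.

**Planted network.**  Beads sit on a ring (neighbour spacing 0.4 nm), so
every bead has exactly two contacts and the planted path — a contiguous arc
— competes with the complement arc; recovery is an inference, not a
connectivity tautology.  Displacements are zero-mean Gaussian, i.i.d.
across axes, with correlation 0.9 between consecutive planted beads and 0.1
between other contacting beads.  Within the planted path, correlations
decay geometrically with path separation (0.9^|i−j|): a matrix with high
nearest-neighbour correlation and zeros beyond is not positive semidefinite
(a nearest-neighbour-only profile requires r ≤ 0.5), so the Markov/AR(1)
profile is the minimal valid completion that preserves every pairwise value
the generator guarantees.  Infeasible requests fail the eigenvalue check
with the offending eigenvalue reported.  Per-bead displacement stds can be
scaled (e.g. ×2 on one arc) to emulate the higher mobility of the distant
cytochrome domain, and the ring can be split into two pseudo-subunits with
per-arc residue numbering so docked-vs-distant flexibility comparisons run
on identical residue ranges, as the real per-copy helix range (1–100) does.

**What passing the synthetic suite shows — and does not.**  The generators
produce stationary, Gaussian-fluctuation, two-state dynamics with known
switching statistics and no rigid-body drift, solvent, membrane or
force-field physics.  Passing tests therefore establish the *estimators*
(occupancy sweep, KDE modes, Kabsch/RMSF, network pathways) against exact
ground truth; they do not certify that a particular real system satisfies
the generators' assumptions, nor do distance statistics by themselves
establish electron-transfer rates or mechanisms.

## Monte-Carlo tolerances

Frames from the switching/OU generators are autocorrelated, so stochastic
checks use the corrected standard error
SE² = p(1−p)/n · (1+ρ)/(1−ρ) with ρ = e^{−(k_AB+k_BA)·dt}, and assert
within 3 SE.  Closed-form OU checks use n = 2×10⁵ (std within 2 %, lag-1/θ
autocorrelation within 0.05 of e⁻¹); mode recovery and RMSF closed forms
use n = 10⁵; planted-pathway recovery is evaluated over 20 independent
generator seeds at 2×10⁴ frames each.  These sizes were chosen so each
check's Monte-Carlo error is several times smaller than its tolerance.

## Pipeline determinism

All randomness flows from one integer seed through `numpy` SeedSequence
spawns (kept below 2³¹).  A pipeline rerun with the same config and seed
produces bit-identical numeric TSV/JSON outputs; the manifest records the
SHA-256 of the canonical config JSON (which includes the output directory)
plus the seed and package version, and contains no timestamps.  Figures are
rendered exclusively from the exported tables, so a report can be
regenerated without recomputation.  Default synthetic problem sizes (six
trajectories of 2×10⁴ frames; 2×10⁴-frame network ensembles) keep a full
run in the tens of seconds on one CPU while leaving Monte-Carlo errors well
inside the stated tolerances.
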