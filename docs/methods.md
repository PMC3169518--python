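# Methods

`hairpintse` analyses coordinate trajectories of a small two-state folding
peptide — the working system is Peptide 1, a designed 15-residue β-hairpin
(SESYINPDGTWTVTE, NPDG type-I turn) — and characterizes its folding
transition state thermodynamically, kinetically and structurally.  This
note records the model, the defaults, the synthetic-data design and the
numerical choices.

## Order parameters

**R parameter.**  For the five native inter-strand Cα pairs of the hairpin
(N6–T10, I5–W11, Y4–T12, S3–V13, E2–T14),

    R = Σ_i  d_i(native) / d_i(frame),

one ratio per pair.  Each term approaches 1 as its pair reaches the native
separation, so R ≈ 5 marks the folded hairpin; an expanded coil has small
ratios and sits near R ≈ 2.  R is invariant under rigid-body motion and is
a backbone-topology coordinate.  Frames with a coincident pair (zero
distance) are rejected as degenerate rather than producing an infinity.

**Q (fraction of native sidechain contacts).**  The native contact list is
derived from the reference conformation, never hard-coded: every residue
pair at sequence separation ≥ 3 whose minimum sidechain heavy-atom distance
is ≤ 0.55 nm.  Q of a frame is the fraction of that list formed under the
same rule.  Sidechain = non-backbone heavy atoms; glycine, which has none,
uses its Cα as proxy (needed for the W11–G9 analysis).  Hydrogens are
excluded for force-field independence.  The separation-≥3 default excludes
trivial i,i+1 / i,i+2 neighbours, standard native-contact practice.

**RMSD.**  Cα RMSD after optimal rigid superposition (Kabsch, SVD with
determinant correction).  Collinear point sets are rejected.

All distances are plain Euclidean distances: input coordinates must be
whole-molecule (pre-imaged); no periodic wrapping is applied.

## Free-energy landscape

Pooled frames are binned on a 40 × 40 grid over an order-parameter plane
(default Q–R).  The Q axis is fixed to [0, 1]; data-scaled axes (R, RMSD)
span the pooled min–max with a right-closed final bin.  With p_i the cell
occupancy probability and p_ref that of the most probable cell,

    ΔA_i = −R T ln(p_i / p_ref)      R = 0.008314 kJ/(mol·K), T = 300 K,

so the folded-state mode is the zero of the surface.  Unoccupied cells
carry an explicit +∞ and are excluded from every statistic.  Ties for the
reference cell break to the lowest (x, y) bin index for determinism.

**Errors.**  Statistical errors use the standard error over M disjoint
trajectory subsets (default M = 3 groups of two trajectories):
σ_M = s/√M with s the sample standard deviation of the per-subset
estimates.  Each subset's ΔA is anchored to the *global* reference cell so
cells are comparable across subsets; a cell unvisited in any subset is
reported unavailable (NaN), never zero.  Convergence traces recompute a
cell's ΔA from all trajectories truncated at the same elapsed time,
reusing the full-data bin edges and reference cell.

## State decomposition

The folded state F is the 8-connected flood fill from the reference cell
over occupied cells within 12 kJ/mol of it; the unfolded state U grows the
same way from the deepest local minimum not reachable from the folded seed
through sub-cutoff cells.  Every remaining occupied cell is transition
state (TS) — the literal barrier-top definition.  An optional ΔA cap can
restrict the TS to a barrier band; it is off by default.  Frames are
labeled by their grid cell.

**TSE refinement.**  A maximal F residence whose mean turn (N6–G9 Cα)
distance exceeds 0.8 nm reached the folded region of the plane with a
clearly non-native turn ("false fold"): it is relabeled U and the TS
excursion that terminated in it is excluded from the reported TSE.  The
0.8 nm default sits between the native turn peak (≈ 0.55–0.60 nm) and
non-native turn geometries; it is exposed in configuration because the
underlying criterion is qualitative.

**Overlap.**  Agreement between TSEs from two coordinate pairs is reported
as |TS_a ∩ TS_b| / |TS_a| with the R–Q labeling as reference a; the
Jaccard variant is also reported, since "overlap" is ambiguous.

## Kinetics

Maximal TS runs flanked by known states are excursions, classified
U-TS-F / F-TS-U (reactive) and U-TS-U / F-TS-F (non-reactive); runs
touching a trajectory boundary are discarded (unknown flank; well under 1%
of events at the scales used).  A run of k frames is scored k·Δt — at
Δt = 10 ps comparable to the lifetime itself, so residences are
quantized.

The TS lifetime τ is the time constant of A·exp(−t/τ) fitted to the
residence-time histogram (bin width = frame interval) by weighted least
squares on ln-counts with Poisson weights; the reported correlation is the
Pearson r between observed and fitted bin heights.  A geometric
maximum-likelihood variant on the raw residences is available
(`method="mle"`).  At least 20 events are required; a single-bin histogram
is a fit error.  τ's uncertainty uses the M = 3 subset scheme above.  The
commitment fraction p_fold is the fraction of excursions whose destination
is F.

Because residences are geometric on the frame grid, the fitted decay
constant — not the arithmetic mean residence — is the right estimator of τ
when τ ≈ Δt; the two converge for τ ≫ Δt, which the tests verify.

## Structural characterization

Ensemble histograms (default bin width 0.02 nm, fine enough to separate
the 0.54 vs 0.72 nm middle-pair peaks) are frame-wise and normalized to
unit mass; peaks are modal bin centers.  The five standard observables are
the turn (N6–G9), middle (Y4–T12) and end-to-end (S1–E15) Cα distances and
the minimum sidechain distances W11–P7 and W11–G9.  The middle pair is
taken as residues 4 and 12 of SESYINPDGTWTVTE, i.e. Y4–T12.

Per-path-class subpopulations pool the TS frames of each class, weighting
long excursions more (frame-wise ensembles).  For F-TS-F the fraction of
TS frames with the middle Cα distance ≤ 0.6 nm — between the folded
(≈ 0.54 nm) and TSE (≈ 0.72 nm) peaks — measures the folding-nucleus
subpopulation.  The prior-to-TS ensemble takes, along forward reactive
paths, the frames within 1 ns before TS entry (clipped at the trajectory
start, TS/F frames excluded), and is disjoint from the TSE by
construction.

## Synthetic data

The generator provides trajectories with the statistical and geometric
structure the analysis assumes, with ground truth for every estimator.

**Kinetics.**  A discrete-time Markov chain at the frame interval:
residence in each state is geometric with per-frame survival
exp(−Δt/τ_state) — the exact discretization of exponential residence with
time constant τ, making the residence histogram decay exactly as
exp(−t/τ), which is what the monoexponential fit estimates.  A TS exit
commits to F with probability p_fold (default 0.527), else U; basin exits
always enter the TS.  Defaults: τ_TS = 10.2 ps, τ_U = τ_F = 2 ns.  The
basin residences are a desk-scale choice giving deep, well-resolved basins
and thousands of excursions per microsecond; they do not reproduce the
peptide's real ~0.8 µs folding time, which is out of scope.  A frame
interval exceeding a basin residence raises a resolution error.

**Fast path (`emit_series_only`).**  (Q, R) are drawn per frame from
state-conditional Gaussians centred at U = (0.10, 2.10),
TS = (0.45, 3.50), F = (0.85, 4.95).  Deviations are truncated per axis at
2.2 σ by reflection, so each basin cloud is compact: conformational basins
have bounded extent, and a basin frame can never masquerade as a
barrier-top outlier.  The default widths are grid-aligned — the U support
tiles 4 × 4 grid cells and the F support 3 × 2 (the folded state being the
narrower, deeper minimum), with the R-axis range set by the two support
extremes — so the flood-filled basins are exactly congruent with the
emitted clouds and the U minimum lands ≈ 2 kJ/mol above the folded mode.
Analytic cell masses (reflected-truncated normal CDFs) combined with the
realized state counts give the expected cell probabilities used by the
thermodynamic consistency check.

**Geometry (`emit_coordinates`).**  One Cα plus one pseudo-sidechain atom
per non-glycine residue (29 atoms).  Pseudo-sidechains sit 0.25 nm off the
backbone on alternating faces, as in a β-strand, and lean 0.045 nm toward
their in-register cross-strand partner, so a formed backbone pair packs
its sidechains inside the 0.55 nm cutoff; the native contact list is then
exactly the six in-register pairs with ≥ 0.10 nm margin.  Template
conformations are solved by least squares on pair-distance targets with
0.38 nm virtual bonds:

* native hairpin — end 0.42, turn 0.55, middle 0.54 nm;
* TS loop — end 0.42, turn 0.60, middle 0.72 nm, W11 key-locked at
  0.55 nm from both P7 and G9;
* exit geometry — the TS loop with the middle closed and W11 released;
* folding nucleus — middle 0.54 nm, loose ends, W11 at 0.30 nm from P7
  (used by 65% of F-TS-F excursions);
* an unfolded coil band (two coil endpoints spanning R ≈ 1.8–2.1, plus a
  turn-formed branch) and the pre-TS conformation — a coil with formed,
  W11-locked turn and ends apart — solved *from* the coil so every
  untouched coordinate stays coil-like.

The turn-peak targets are deliberately asymmetric (F 0.55 vs TSE
0.60 nm): the turn is native-like at the barrier but slightly looser than
in the folded state.

Mechanism encoding: the last 1 ns (100 frames) of every U residence before
a TS entry adopts the pre-TS conformation through a 5-frame ramp — turn
first, ends still apart; TS entry then forms the end contact as a jump;
forward reactive (U-TS-F) crossings morph their last up-to-5 TS frames
toward the exit geometry — concerted middle closure and W11 release —
before snapping into the native state.  Per-state isotropic coordinate
noise (clipped at 3σ; U/TS 0.015 nm, F 0.005 nm — the folded hairpin is
rigid) keeps within-conformation order-parameter jitter inside one grid
cell; unfolded-state heterogeneity comes from the coil band instead.

**What the generator does not emulate.**  Memoryless TS kinetics means
reactive and non-reactive excursions share one residence distribution,
unlike real barrier dynamics where non-reactive touches are shorter.  The
toy chain has 6 native contacts, so Q is coarse (steps of 1/6) and the
folded basin occupies a single Q column; real sidechains give ~20 contacts
and a broader basin.  Within-state fluctuations are uncorrelated in time.
There is no solvent, force field or temperature dependence.  Passing tests
therefore validate the estimators — binning, inversion, flood fill,
segmentation, fitting, ensemble statistics — not any physical prediction
about real trajectories, whose basin tails and autocorrelation will blur
state boundaries more than the toy data do.

## Problem sizes

Unit and property tests run on 6 × 0.05 µs fast-path series and
6 × 0.05 µs coordinate runs (tens of excursions).  The kinetics-recovery
and thermodynamic-consistency checks use 6 × 1 µs fast-path runs
(~3,000 excursions, ~10 s); the structural acceptance computation uses
6 × 0.2 µs coordinate runs (~1,000 TSE frames, ~40 s).  These sizes are
the package's desk-scale defaults; all scale linearly.

## Numerical notes

* Histogram edges are integer multiples of the bin width, with a guard for
  float round-down of the top edge (mass is never silently dropped).
* PDB I/O converts Å ↔ nm; internal units are nm and ps throughout.
* The lifetime fit refuses non-decaying histograms; subsets too small to
  fit are skipped in the error estimate (τ error NaN when fewer than two
  remain).
* Template solving verifies every target to 2 × 10⁻³ nm and names the
  violated constraint on failure.
* All randomness flows from one integer seed through per-trajectory
  spawned generators; reruns are bit-identical.
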