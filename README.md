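# hairpintse

Transition-state-ensemble (TSE) analysis of two-state peptide folding
trajectories.

Small fast-folding peptides cross a single free-energy barrier between the
unfolded (U) and folded (F) states.  Everything interesting about *how*
they fold — whether the barrier is reached by random fluctuations or by an
ordered sequence of structural events — lives in the transition state, a
short-lived ensemble that plain structural analysis never isolates.  This
package implements the complete post-simulation pipeline for extracting
and characterizing that ensemble from equilibrium coordinate trajectories
of a 15-residue β-hairpin (Peptide 1, SESYINPDGTWTVTE):

* **Order parameters** — the inter-strand distance-ratio parameter
  R = Σᵢ dᵢ(native)/dᵢ(frame) over the five native Cα pairs (R ≈ 5 when
  folded), the fraction of native sidechain contacts Q (minimum sidechain
  distance ≤ 0.55 nm), and Cα RMSD after Kabsch superposition.
* **Free-energy landscape** — Boltzmann inversion
  ΔA_i = −RT ln(p_i/p_ref) of the 40 × 40 occupancy histogram over the
  (Q, R) plane at 300 K, with per-cell errors from three independent
  trajectory subsets and time-convergence traces.
* **State decomposition** — F and U as 12 kJ/mol flood-filled basins
  around the two free-energy minima; every other occupied cell is TS.
  Includes refinement that expels "false folds" (non-native-turn
  conformations inside the folded region) from the TSE, and the TSE
  overlap between alternative coordinate planes (R–Q vs RMSD–Q).
* **Kinetics** — segmentation of TS excursions into the four crossing
  scenarios (U-TS-F, F-TS-U, U-TS-U, F-TS-F), a monoexponential fit of
  the residence-time histogram giving the TS lifetime τ, and the
  commitment fractions p_fold / p_unfold.
* **TSE structure** — turn/middle/end-to-end Cα distance distributions,
  the non-native W11 "key-lock" contacts with the turn residues P7/G9,
  per-path-class subpopulations (including the folding-nucleus fraction of
  F-TS-F), the 1-ns prior-to-TS ensemble, and reactive-path time courses.
* **Synthetic data** — a generator producing three-state (U/TS/F)
  trajectories with exponential residences, configurable branching, and
  toy hairpin geometries that encode the turn-first / ends-at-the-TS /
  middle-last mechanism, with ground truth for every estimator.

No public trajectory data exist for this system, so the package is
validated end-to-end against the generator, whose defaults are the study's
stated conditions (τ_TS = 10.2 ps, p_fold = 0.527, basins at
(Q, R) = (0.10, 2.10) and (0.85, 4.95), TSE distances end ≈ 0.42 /
turn ≈ 0.60 / middle ≈ 0.72 nm).  See `docs/methods.md` for the model and
its assumptions.

## Worked example

```sh
python analysis/01_simulate.py      # generate the synthetic dataset
python analysis/02_landscape.py     # free-energy surface + errors
python analysis/03_kinetics.py      # excursions, lifetime, commitment
python analysis/04_structure.py     # TSE structure on toy geometry
```

The kinetics step prints, for the default seed:

```
2937 TS excursions
TS lifetime tau = 10.24 +/- 0.20 ps (monoexponential fit, correlation 0.99958)
commitment: 52.8% to F, 47.2% to U
  UTSF:   745 excursions, mean residence 16.0 ps
  FTSU:   743 excursions, mean residence 15.9 ps
  UTSU:   644 excursions, mean residence 15.6 ps
  FTSF:   805 excursions, mean residence 16.1 ps
```

i.e. from six 1-µs trajectories the pipeline re-derives the lifetime the
generator was configured with (10.2 ps) to within its subset error, and
the 52.7/47.3 commitment split within binomial noise.  The structure step
reports the TSE's loop-like topology — ends and turn in contact
(0.43 / 0.61 nm modal distances) while the middle strands are apart
(0.73 nm vs 0.55 nm in F) — the W11 key-lock contact (0.55 nm to both P7
and G9) already present in the 1-ns prior-to-TS ensemble, and the
folding-nucleus subpopulation of F-TS-F (middle contacts formed in ~2/3 of
its TS frames).

The same stages are available as a CLI (`hairpintse simulate | orderparams
| distance | landscape | states | paths | run`) for use on external
multi-model PDB trajectories.

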