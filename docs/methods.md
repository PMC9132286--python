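# Methods

## Scope and model

flexiscreen operationalizes a flexibility-guided stability screen for
enzyme variants. All statistics are computed over a *conformational
ensemble*: an ordered set of frames sharing one topology, read from
multi-model PDB. The package consumes ensembles and design-score tables;
it never runs a simulation engine or a design protocol itself, and it
never computes Rosetta energies (ΔΔG values are inputs, in REU).

### Superposition and flexibility metrics

Rigid-body fits use least-squares (Kabsch) superposition restricted to a
configurable atom selection (`calpha` default, `backbone`/`heavy`/`all`
available). Ensembles are aligned by iterating "fit every frame to the
running average, recompute the average" until the average moves less than
`tol` (default 1e-4 Å RMS, `max_iter` 10). This iterative-mean reference
is the standard convention when no external reference exists; the fit is
deterministic and a non-converged iteration returns the last iterate with
a warning.

Per-residue RMSF is
`sqrt(mean over frames and selected atoms of |r − ⟨r⟩_time|²)`,
i.e. the mean square displacement is averaged over a residue's selected
atoms *before* the square root. The default Cα selection is the dominant
convention for per-residue flexibility profiles; heavier selections are
exposed because published region averages do not state the selection.

The *centroid* frame of a window is the frame with minimum fitted RMSD to
the window's average structure, ties broken to the earliest frame (frame
windows are half-open `(start, stop)` intervals; time-based windows are
resolved through the ensemble's optional frame times before this call).

### Flexible regions

The flexibility cutoff is the arithmetic mean of the *pooled* per-residue
RMSF over all supplied (replicate) profiles. Residues strictly above the
cutoff are flagged; residues at the cutoff are not. Flagged residues
merge into maximal runs of consecutive residue numbers (`gap_tolerance`
default 0, the strictest reading of "adjacent"); configured exclusion
intervals — typically an intrinsically floppy C-terminus — are removed
before merging. Regions are ranked by mean RMSF, descending, ties to the
smaller region id, and the top *k* (default 5) become design targets.
With replicate profiles, a residue is flagged on its replicate-mean RMSF,
and region summaries report the mean of replicate region-means ± the
sample sd across replicates; the across-residue sd is available through
`summarize_region`.

A position is *designable* iff its minimum atom-pair distance to any
catalytic residue (defaults: 442 and 712) is strictly greater than 15 Å.

### Design selection and ΔRMSF screening

From a design table, at most one mutant call survives per position: the
design with minimum ΔΔG (ties to the alphabetically first designed
residue), kept only if ΔΔG < 0 REU, skipping rows whose design is absent
or identical to the native residue.

Regional ΔRMSF is defined on region-*mean* RMSF —
`100·(⟨RMSF⟩_mut − ⟨RMSF⟩_wt)/⟨RMSF⟩_wt` — rather than as a mean of
per-residue percent changes, because region-mean values are what the
upstream summaries report. Replicates pair index-wise (all pairs when
counts differ); the replicate mean ± SEM (sample sd/√n) is the screening
statistic. Stage thresholds are configuration with defaults −10.0 %
(high-temperature stage) and 0 % (optimum-temperature stage); both
comparisons are strict.

### Hydrogen bonds

Donors are N/O heavy atoms with a hydrogen within 1.2 Å (distance-based
bond inference, since MD-derived PDBs rarely carry CONECT records);
acceptors are all N/O. A bond exists in a frame iff donor-heavy to
acceptor distance ≤ 3.5 Å *and* the D–H⋯A angle measured at the hydrogen
is ≥ 120°, both inclusive (a 1e-9 slack absorbs floating-point round-off
at the boundaries). Pair identity for occupancy is (donor heavy atom,
acceptor atom): alternative hydrogens of one donor count once per frame.
Intra-residue pairs are excluded. Occupancy is the percentage of frames
detected; strength classes are strong (> 75 %), medium (75–50 %], weak
(50–25 %], very weak (25–10 %]; at or below 10 % a pair is unreported.
Region summaries count reported bonds with at least one partner residue
inside the region; the other partner is unrestricted by default and can
be limited to residues within a `neighbor_cutoff` of the region in a
reference frame.

### Secondary structure

A self-contained simplified DSSP: backbone N–H→C=O bonds are scored with
the Kabsch–Sander energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN)` kcal/mol, bonded iff E < −0.5. Consecutive n-turns (n = 3, 4, 5)
yield helices, bridge patterns (parallel and antiparallel) yield strands,
and the 8-state classes collapse to three: {H, G, I} → helix, {E, B} →
sheet, else coil — matching the three categories reported for region
summaries. Amide hydrogens are synthesized opposite the bisector of
C(prev)–N–Cα at 1.01 Å when missing; chain-start residues never donate
(the Kabsch–Sander convention), and pattern search restarts after chain
breaks (C–N distance > 2.5 Å or a chain-id change). Region percentages
are per-frame state fractions averaged over frames, then mean ± sample sd
across replicates. Solvent accessibility and an 8-state surface are out
of scope.

## Synthetic ensembles

The generator emulates only the *marginal conformational distribution*
that every downstream statistic depends on — not kinetics, force fields
or temperature. A polyalanine backbone (N, H, Cα, C, O; standard bond
lengths/angles; φ/ψ = −57°/−47° helix, −139°/135° strand, −75°/145°
PPII-like coil) is perturbed by independent per-atom Gaussian
displacements with prescribed per-residue σ (Å per coordinate), so that
without superposition E|Δr|² = 3σ² and RMSF = σ√3 exactly in expectation.
Region scaling multiplies σ inside an interval; a "mutant" is an
independent ensemble with region σ scaled by *s*, giving expected
regional ΔRMSF = 100·(s − 1) %. Planted hydrogen bonds move the
acceptor's backbone O to D–A 2.9 Å at a 165° angle in exactly
`round(occupancy/100 · n_frames)` frames (per-frame Bernoulli draws
optionally) and to 4.5 Å otherwise — unambiguous with respect to the
3.5 Å/120° criteria. A two-chain antiparallel sheet is built by pairing a
strand with its copy rotated 180° about the sheet normal, register chosen
by a deterministic grid search over rigid offsets maximizing inter-strand
O···N contacts.

Because frames are i.i.d. and displacements isotropic, passing tests on
synthetic data demonstrate the *estimators* (RMSF, occupancy, ΔRMSF,
region calls) are correct, not that real trajectories — with correlated
frames, anisotropic motion and conformational substates — would give the
same uncertainties. Generators are seeded (NumPy PCG64); equal seeds give
bit-identical ensembles.

## Problem sizes and numerical choices

Tests and the acceptance script use small systems chosen to keep the
statistical tolerances meaningful: 2000 frames for the σ√3 closed form
(±5 %), 1000 frames for amplitude-ratio and Bernoulli-occupancy recovery,
700-frame triplicates for ΔRMSF recovery (±2 SEM), 8–24-residue toys for
geometry. The DSSP oracle suite perturbs ideal helix/strand/coil/mixed/
sheet geometries with 0–0.2 Å coordinate noise; at 0.2 Å a sheet's
Kabsch–Sander energies sit near the −0.5 kcal/mol threshold, so small
implementation differences (hydrogen placement) produce the residual
few-percent disagreement with the reference implementation.

Degenerate inputs: superposition requires ≥ 3 non-collinear atoms
(singular-value check, error otherwise); a zero wild-type region mean
makes ΔRMSF undefined (error); models without hydrogens yield an empty
donor list with a warning, signalling that occupancy criteria cannot be
evaluated; residues missing from a selection are omitted from RMSF
profiles with a warning.

## Known limitations

- No mmCIF or binary trajectory formats (DCD/XTC) in v1; multi-model PDB
  only.
- No mass-weighting, covariance/PCA fluctuation analysis, B-factor or
  normal-mode flexibility measures.
- The hydrogen-bond module is purely geometric; no energetic or
  salt-bridge/hydrophobic-contact analysis.
- Published region-level RMSF magnitudes from long MD runs are not
  reproducible here by construction — the pipeline reproduces the
  *selection logic* exactly and validates the estimators on synthetic
  ensembles with known ground truth.
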