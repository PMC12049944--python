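# Methods

## The belt model

The double belt is idealized as two rings of one anchor point per residue.
Chain A residue *i* sits at azimuth *i·Δθ* (Δθ = 2π/N) on a circle of
radius C/2π at height +s/2; chain B runs in the opposite direction at −s/2,
phased so that residue *c − i* shares residue *i*'s azimuth. The registry
constant *c* defaults to 263, which maps the helix-5 span (121–142) onto
itself end-to-end and makes helix 4 face helix 6 at the two interface
sites; it is an explicit parameter because the pairing arithmetic is a
modelling choice, not a measured quantity, and alternative registries
should be testable.

**Rise per residue.** An ideal α-helix rises 1.5 Å per residue, but
1.5 × 22 = 33 Å per helix over-predicts the measured circumference growth
of the helix-5-duplicated mutant (~24 Å). The model therefore treats the
rise as free, with two natural settings: "ideal" (1.5 Å) and "effective"
(measured circumference / monomer length, ≈1.09–1.24 Å). The discrepancy is
real — belts on particles are not ideal helices — and is surfaced rather
than hidden: belts are normally built from measured circumferences, and the
constant `RISE_IDEAL` documents the alternative.

**Belt separation** (axial gap between the rings) defaults to 15 Å, a
round figure for two stacked amphipathic helices at a bilayer edge; no
distance computed here is sensitive to it at the ±5 Å level except the
inter-chain spans of registry-adjacent pairs.

**Helix-5 duplication.** `insert_segment_repeat` inserts a tandem copy of
a segment in each monomer, preserving the rise (circumference grows by
L × rise), shifting downstream numbering by L (an old→new map is returned,
since mutant results are usually discussed in wild-type numbering), and
shifting the registry constant by L so the doubled block re-registers onto
itself and the 4/6 interfaces survive in the new numbering.

**Spacing predictions.** Site centers are the azimuths of the
registry-paired helix 4 and helix 6 midpoints (the interface centers).
`predict_spacing` reports the chord and arc between two site azimuths at
radius (belt radius + radial offset). The *shift* in chord between the
wild-type and mutant belts built at their measured circumferences
reproduces the ~26 Å observed spacing change for radial offsets in the
10–20 Å range (default 15 Å, a mid-rim contact depth; sensitivity ≈
0.33 Å per Å of offset). At the ligand's half-width (~27 Å) the curved
model over-predicts the shift by ~4.5 Å while reproducing the ~81 Å
absolute wild-type spacing — the flat-belt arithmetic (shift = inserted
arc) and the curved chord model bracket the measurement, and
`geometry_consistency` defaults to the flat limit, which is the
back-of-envelope the measured 24 Å vs 26 Å comparison itself uses.

**Known inconsistency.** The printed particle circumferences (300/324 Å)
are not exactly π × the printed diameters (~94/100 Å); the package treats
circumferences as authoritative for arc arithmetic and exposes
`ParticleGeometry.check` so callers can pick their own tolerance. Whether
the minor ~150 Å spacing population is a third site or a projection
artifact is left open, as the data leave it.

## Cross-link filtering

A link is keyed by its order-normalized residue pair plus chemistry (the
identification is of a residue pair, not a peptide pair — the finest
granularity the downstream distance analysis can use). The
reproducibility rule keeps a key only if present in every replicate with
*every* supporting observation within the ppm tolerance; the 5 ppm
boundary is inclusive ("within 5 ppm" read as ≤). Upstream spectral FDR
is treated as already applied; scores are carried, not re-thresholded.

EDC is heterobifunctional: a valid link needs one acidic end (D/E) and one
amine end (K or a protein N-terminus). Protein N-termini count as amine
ends for all three reagents. The dynamic-region exclusion defaults to the
scaffold's N-terminal residue only, with a configurable range because the
first ~7 residues are also plausibly mobile.

## Calibration

Spans are Euclidean distances between reference atoms; the default atom
rule is Cα everywhere, with a Cβ option (glycine and coarse models fall
back to Cα). The source conventions conflict (contact plots quoted at Cα,
calibration once at Cβ); a single switchable default avoids silently mixed
conventions, and results report which rule produced them. For multi-copy
structures the minimum over chain assignments is used — a cross-link cannot
tell copies apart — with the per-assignment breakdown retained. SD is
population SD by default (switchable); with a single span the SD is 0 and
the constraint equals the span. The contact threshold is strictly < 24 Å;
the diagonal is true. NMR-style multi-model files use the first model.

## Rigid-body restraint screening

The scan enumerates a deterministic quasi-uniform rotation set
(super-Fibonacci spiral — closed form, no RNG, so scans are bitwise
reproducible; the set's maximum nearest-neighbour angle is reported as the
angular-gap proxy) against a translation lattice covering every placement
that could touch the interaction shell. Accessibility is grid-based: the
fixed structure is voxelized (default 2 Å), a Euclidean distance transform
gives each voxel's distance to the fixed body, and a pose is accessible
when (a) at most `clash_overlap_max` scanning atoms fall in occupied
voxels, (b) the nearest scanning atom is within the interaction shell, and
(c) optionally no scanning atom comes closer than `collision_radius` (a
hard-sphere clearance for coarse bead models whose voxel occupancy is
sparse). Restraint distances are exact Euclidean distances;
`complexes_consistent_with_n[N]` counts accessible poses satisfying ≥ N
restraints and is non-increasing in N by construction.

False-positive flagging z-scores each restraint's satisfaction fraction
against the mean and population SD across restraints and flags z < −1 by
default. This is this package's own statistic — deliberately simple and
documented here — and makes no claim of numeric equivalence with other
accessible-interaction-space tools' scores. With all fractions equal the
SD degenerates and nothing is flagged (reported as a warning). Grid sizes
stay at desk scale (≤ ~100³ voxels); there is no FFT acceleration, no
energy function, no flexible docking and no EM-map handling.

## Spacing mixtures

Distances are fit with a k-component (default 2) normal mixture by EM on
the raw values — no histogram binning, which removes a bin-width choice;
bin width appears only in plots. Initialization is deterministic (means at
the 25th/75th percentiles, pooled SD, equal weights); 5 seeded restarts
draw initial means from the data and the best final likelihood wins.
Convergence is relative log-likelihood change ≤ 1e-8 (cap 500 iterations);
component SDs are floored at 0.5 Å so degenerate samples collapse to a
single effective mode instead of a variance blow-up. The *major mode* is
the largest-weight component (ties to the smaller mean). Mode-shift
uncertainty is a percentile bootstrap (default 1000 resamples) with
warm-started single-run EM refits; unconverged fits are refused rather
than compared.

## What the generators emulate — and what they don't

`simulate_spacing` draws from the two-component truth the measurements
describe: wild-type modes 81/150 Å with weights 0.85/0.15, mutant major
mode 107 Å. The mutant *minor* mode (176 Å = 150 + the 26 Å shift) and all
component SDs (10 Å) are assumptions, flagged as such in the truth
metadata — no minor-mode mutant value was reported. n = 250 per condition
is the scale of a negative-stain particle set.

`simulate_crosslinks` plants true links among chemically reactive pairs
whose structural span fits the reagent's limit (with Gaussian selection
noise, SD 2 Å) and false positives among reactive pairs exceeding the
limit by > 10 Å; per-observation mass errors are N(0, 2 ppm) truncated at
±8, so the 5 ppm filter passes ~99% of true observations; dropout is
per-link-per-replicate. What it does not emulate: peptide-level
detectability, intensity-dependent scoring, correlated replicate failures,
or decoy-database score distributions — so passing recovery tests shows
the *filters* behave as specified, not that real spectra would.

`make_belt_lcat_scene` places a ~50×60×60 Å ellipsoidal bead decoy (36
surface + 3 interior beads) tangent to the belt at a site azimuth, over a
fixed structure that includes a solid pseudo-lipid disc filling the
particle body (the scanned particle is protein *and* lipid; without the
disc, poses threading the thin bead ring between decoy beads would be
spuriously clash-free). True restraints run from belt-facing surface beads
to their nearest belt residues at the calibrated 26 Å limit, all
satisfiable at the planted pose. Planted false positives anchor the
buried central bead: its 25 Å burial plus the hard-sphere contact
clearance exceeds the 26 Å span in essentially every clash-free pose,
which is precisely the geometric signature that lets a marginal
satisfaction-fraction statistic catch a spurious identification. Scene
scans in the test suite run at voxel 3 Å / 16 rotations / 5 Å steps with
an 8 Å shell and 5 Å collision radius — coarse enough to finish quickly,
fine enough that the true/false fraction gap (~2% vs ~0.02%) is
unambiguous.

Every generator is a pure function of (arguments, seed); truth metadata
suffices to score any recovery statistic without reading generator
internals.

## Numerical conventions

Inclusive 1-based residue ranges throughout. Azimuth arithmetic is modulo
2π with minimal-angle differences; arc distances are reported at the
radius where they are measured, and chord ≤ arc holds at any fixed radius.
Voxel round-trips are exact to half a voxel per axis; accessibility counts
are exactly reproducible against a naive pose enumerator because both
paths share the same documented grid definition. Ranking outputs
(discordant regions, flags) break ties deterministically so results are
independent of input order.
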