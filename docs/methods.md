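# Methods

`tomospat` analyses particle tables produced by subtomogram averaging — one
record per detected macromolecule with a tomogram identifier, a 3D centre
position and a ZYZ Euler orientation — and asks four questions about the
spatial organisation of a chaperonin (TRiC/CCT) population inside cells: do
particles of a given conformational state form clusters, are clustered
neighbours oriented towards each other in a preferred way, are particles
enriched on the exit-tunnel side of nearby ribosomes, and how do the
conformational-state tallies distribute across the duty cycle. A synthetic
particle-field generator with known ground truth closes the loop: every
statistic the package computes can be calibrated against fields whose
structure is known by construction.

## Units and conventions

All positions are nanometres; voxel-unit tables are converted exactly once,
on ingest, using an explicit pixel size (the reader refuses to guess the
binning of a table). Orientations are intrinsic ZYZ Euler triplets in
degrees, composed as `R = Rz(phi) @ Ry(theta) @ Rz(psi)` — the rot/tilt/psi
composition of RELION particle tables. Only *relative* rotations between
particles enter any statistic, so the analysis results are invariant to the
choice of a consistent convention; this one is pinned for round-trip
determinism, with the `psi = 0` tie-break at gimbal degeneracy
(theta ≈ 0 or 180°). No symmetry reduction (the chaperonin's pseudo-D8) is
applied to orientations; relative rotations are analysed as recorded.

## Cluster tracing

A cluster is ≥ 2 particles of one state, inside one tomogram, connected
under a centre-to-centre distance rule. Membership is defined as the
single-linkage connected component of the distance graph: with a plain
cut-off `t` (default 20 nm) an edge joins particles at distance ≤ t; in
threshold sweeps (grid 15–40 nm) each grid value `t` uses the closed
interval [t − 0.5, t + 0.5] nm, so a distance on a boundary belongs to both
adjacent bins. Components give an order-independent partition; the greedy
closest-unvisited chain from the lowest-id member is kept as the member
*ordering* only, because at the sparse densities involved the chain walk
and the component view coincide. 15 nm is treated as the physical minimum
centre-to-centre distance of two chaperonin complexes (hard core).

Pair statistics (per-length counts, mean and n−1 standard deviation of
consecutive link distances) are restricted to links in [15, 20] nm. A
single qualifying link reports sd 0 with an explicit flag rather than NaN.
Topology labels are a deterministic rule: pairs are linear by convention;
for k ≥ 3, *circular* if the chain endpoints close under the active
distance rule, otherwise *linear* if end-to-end distance ÷ summed link
lengths ≥ 0.8, else *other*. Filament proximity counts a cluster as close
to a track (e.g. an actin filament trace) if any member is within 20 nm of
any track point in the same tomogram.

## Relative-orientation analysis

For each cluster member the rotation of its nearest in-cluster neighbour is
expressed in the member's frame (`R_ref^-1 @ R_nb`), the reference vector
(0, 0, 1) is rotated by that relative rotation, and the resulting unit
vector is mapped to a planar disc by two-sided stereographic projection:
z > 0 to the northern map (x, y)/(1 + z), z ≤ 0 to the southern map
(x, y)/(1 − z). Identically oriented neighbours land on the north pole.
Hemisphere histograms use ~48 equal-area cells (equal-area rings × equal
sectors), reported as densities so a uniform field is flat.

Uniformity is tested with the length of the mean pole vector (a
Rayleigh-type resultant in [0, 1]) against a Monte-Carlo null of the same
sample size drawn uniformly on the sphere; the p-value is
(1 + #{null ≥ observed}) / (n_boot + 1), deterministic given the seed. By
default each member contributes one sample, so an isolated pair is counted
once per direction; these mirrored samples are *dependent* (they share the
same two rotations), which inflates the resultant relative to an
independent-sample null. For calibrated inference the `dedup=True` option
keeps one sample per unordered pair; with deduplicated samples the test's
type-I error is at the nominal level (verified at α = 0.05 over 200
synthetic uniform scenes), and the double-counted mode is retained for
per-particle bookkeeping and plotting.

## Ribosome exit-tunnel-side (ETS) enrichment

Each particle pairs with its nearest ribosome within 100 nm (directed
pairing — ribosomes outnumber chaperonins, so one ribosome can serve
several particles). The particle position is expressed in the ribosome's
zero-rotation frame with the exit tunnel at the origin:
`R_ribo^-1 @ (x − tunnel)`, where `tunnel = ribo_centre + R_ribo @ offset`.
The tunnel offset in the zero-rotation frame is a configuration input; the
default (0, 0, −25) nm stands in for a 60S exit-tunnel position ~25 nm from
the ribosome centre and should be overridden when a calibrated offset from
a ribosome average is available. The ETS/non-ETS boundary is the plane
through the ribosome centre orthogonal to the centre-to-tunnel axis (the
boundary itself counts as non-ETS); only enrichment relative to this
half-space split is claimed, so the analysis is insensitive to the offset
magnitude and to any finer tunnel geometry. Uncertainty on the ETS fraction
is a seeded percentile bootstrap resampling particles (the unit of
analysis), with a per-distance-bin breakdown.

## Duty-cycle accounting

State percentages are computed over *all* particles (open + closed), which
is how the in-cell tallies are conventionally quoted: with the published
untreated counts (2,395 / 875 / 83 open with 0/1/2 prefoldin, 4,054
closed; total 7,407) this yields 45.3% open / 54.7% closed, ~12% single-PFD
and ~1% double-PFD; the treated counts (2,334 / 1,287 / 164 / 3,418; total
7,203) yield ~18% and ~2%. Condition comparisons report percentage-point
deltas with pooled two-proportion z-tests and no multiplicity correction
(documented; the per-state tests are marginal).

## Synthetic generator

The generator emulates the statistical structure of the in-cell
annotations, not their imaging physics. Per tomogram (box 800 × 800 × 150
nm, an analysable lamella volume; absolute size matters only through
density) it draws Poisson particle counts with means anchored to the
published datasets (untreated: 4,054 closed and 3,353 open over 360
tomograms → ~11.3 and ~9.3 per tomogram; treated: 3,418 / 3,785 over 352).
A binomially drawn fraction of closed particles (preset 0.30 untreated,
0.19 treated) is placed as clusters; a drawn target of exactly 1 is rounded
to 0 or 2 with equal probability, since a single particle cannot form a
cluster and silently dropping it would deflate the realized fraction.
Cluster lengths follow a truncated geometric law on 2..7 with ratio 0.45,
approximating the published per-length profile (326, 218, 74, 35, 16, 4
clusters of length 2..7, whose successive ratios average ~0.42 and are not
exactly geometric). Links are drawn from Normal(17.35, 1.18) nm truncated
to [15, 20] — note truncation makes the *realized* moments ≈ 17.38 / 1.06
nm — with uniformly random step directions (no preferred turning angle);
10% of k ≥ 3 clusters are placed as closed rings of equal spacing.
Everything else is hard-core CSR: uniform rejection sampling with a 15 nm
minimum distance to every placed particle. Orientations are Haar-uniform by
default, or concentrated (axis-uniform rotations with angle ~ N(0, 20°)
about a common base) for power studies.

Ribosome scenes place ribosomes hard-core (25 nm) with Haar orientations;
each associated particle picks a ribosome, draws its side (ETS with
probability `p_ets`, preset 0.551 untreated / 0.5 treated and null) and is
placed 20–35 nm from the centre in a direction matching the drawn side
under exactly the classifier's half-space rule. A placement is accepted
only if the chosen ribosome is strictly the nearest, so directed pairing
downstream recovers the drawn side exactly.

What the generator does *not* emulate: missing-wedge and lamella-edge
anisotropy, detection false negatives/positives, membranes and organelles
as excluded volumes, polysome geometry, and boundary corrections (particles
may sit at the box edge; neither generator nor analyser corrects for edge
effects — a bias shared by both, matching the analysis the pipeline
mirrors). Passing calibration on these fields therefore validates the
statistical machinery, not detection robustness on real tomograms.

## Problem sizes and numerical choices

Calibration and recovery checks run at 100 simulated tomograms
(~1,000–2,000 particles, ~3,000 ribosome pairs), 200 replicate scenes for
the type-I-error check and 100 seeded scenes for bootstrap coverage —
sizes chosen to make 3σ binomial bands a few percentage points wide while
keeping a full run in seconds. Tolerances: rotation round-trips to 1e-9,
frame-transform isometry to 1e-9, I/O round-trips to 1e-6, orthonormality
validation at 1e-6. Cluster-fraction recovery subtracts the leakage
measured on the matched CSR-null preset (background particles landing
within 20 nm of each other or of injected clusters; ~0.3–0.5% at the
untreated density). Degenerate inputs are explicit errors or flagged
statuses, never silent NaNs: empty state selections, single-particle
tomograms, zero pairable particles and < 10 orientation samples all
surface as typed exceptions or flagged rows.

## Known limitations

- Coordinates are assumed correct; no uncertainty on particle positions or
  angles is propagated.
- The ETS split is a half-space through the ribosome centre; a curved
  tunnel-proximal surface would classify near-equatorial particles
  differently.
- The uniformity test targets unimodal concentration (resultant length);
  it has no power against antipodally symmetric alternatives, which would
  require a Bingham-type statistic.
- Threshold-sweep membership uses the windowed (±0.5 nm) rule by default;
  the cumulative (≤ t) rule is available and monotone, and the two answer
  slightly different questions about spacing structure.
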