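# Methods

## Alias-position model

An SMS acquisition with multiband factor M partitions the nz slices into
nz/M simultaneous groups.  Grouping follows the contiguous-stride
convention used by vendor SMS sequences: with stride g = nz/M, slice z is
excited together with {z mod g, z mod g + g, …, z mod g + (M−1)g}.  The
reference protocol (68 slices, MB4) therefore has 17 groups of stride 17.

For a source voxel, one leakage alias is expected in each slice of its
group, displaced along the phase-encode (PE) axis by the CAIPIRINHA
inter-slice shift (FOV/k)·m mod FOV, with k = 3 by default and the
slice-offset index m = 1…M counting the group slices in cyclic ascending
order starting after the source slice (so m = M is the source slice
itself, the intra-slice alias).  With in-plane GRAPPA acceleration
(R > 1), each of those positions acquires an additional ghost FOV/2
further along the PE axis, giving 2M predicted positions in total.  All
arithmetic is in voxels modulo n_pe, the matrix size along the PE axis;
the non-PE in-plane coordinate and the slice assignment are untouched.
Positions that land back on the source voxel (which happens whenever
m ≡ 0 mod k, e.g. m = 3 with k = 3) are emitted and flagged rather than
dropped — the indexing m = 1…M is exposed exactly as defined, degeneracy
included.

Two conventions the model leaves open were fixed as follows:

- **Coordinates** are 0-based voxel indices, x fastest-varying, matching
  NIfTI array indexing.  No world-coordinate (affine) reasoning is done;
  affines pass through I/O unmodified, because the aliasing geometry
  lives on the acquisition grid.
- **PE polarity** (P≫A vs A≫P, R≫L vs L≫R) does not move alias
  positions — aliasing is modulo-FOV and sign-free — so both polarities
  map to one axis name ("y" for anterior–posterior, "x" for left–right).
  Polarity only changes the direction of susceptibility distortion, which
  is out of scope.
- **Non-integer shifts.**  If n_pe/k is not an integer the shift is
  rounded to the nearest voxel with a warning (the error is at most half
  a voxel).  The FOV/2 GRAPPA ghost requires an even PE matrix and is a
  hard error otherwise.

## Region masks

Each predicted (or control) position is interrogated through an in-plane
Euclidean lattice disk: integer offsets with dx² + dy² ≤ ⌊d/2⌋², d odd.
For the standard diameter d = 7 this contains exactly 29 voxels; d = 5
gives 13, d = 1 the center alone.  Disks abutting the grid edge — common
for eye-adjacent positions — are clipped to the grid with a warning and a
reduced voxel count rather than rejected.

Control regions are placed by a seeded uniform draw over all brain-mask
voxels at Euclidean distance ≥ `min_distance` (default 10 voxels) from
every predicted alias center; chosen controls are additionally kept at
least one disk diameter apart so they never overlap.  Manual placement
was replaced by the seeded draw purely for reproducibility.

## Quantification statistics

**Variance map.**  Per-voxel sample variance (denominator n−1, the
unbiased estimator) over the full time axis.  High-variance foci away
from the source flag candidate artefact sites.

**Block statistic.**  For each voxel, d(t) = S(t+1) − S(t) and
p(t) = 100·d(t) / max_τ|d(τ)|, the maximum taken per voxel over the
entire run, so |p| ≤ 100 with equality at the argmax.  Constant voxels
(zero maximum change) are defined to give p ≡ 0: they carry no artefact
evidence.  The statistic is invariant to voxel-wise affine rescaling
S → aS + b, a > 0.

Volumes are assigned to task blocks by their midpoint acquisition time
(t + 0.5)·TR, which rounds 20 s blocks (13⅓ volumes at TR 1.5 s) without
bias.  A volume pair (t, t+1) contributes to a condition only when both
volumes carry that condition's label; boundary-spanning pairs are dropped
from both conditions so blink-to-rest transitions contaminate neither.
The region's on-block and off-block scores are the means of |p| over
(mask voxels × assigned pairs), and the artefact intensity is their
difference, in percentage points.  No motion correction, detrending or
ICA is applied inside the statistic; it quantifies the series as
acquired.  When several runs are supplied, the per-region difference is
aggregated across runs as mean ± SEM.

## Synthetic leakage generator

The simulator emulates the forceful-blinking experiment, not the MR
physics.  On an ellipsoidal head phantom (semi-axes 0.35/0.46/0.48 of the
grid extent — deliberately narrower left–right than anterior–posterior)
with uniform tissue intensity (default 1000 a.u. on a 0 a.u. background),
an anterior "eye" disk is added to the head surface.  During task-on
volumes the eye signal jumps by an independent zero-mean Gaussian draw
with standard deviation `source_amplitude` (default 100 a.u.); during
rest it is flat.  An abrupt, sign-varying fluctuation was chosen over a
smooth haemodynamic response because the block statistic measures
volume-to-volume change, which a smooth response would under-excite; the
varying sign also reproduces the mixture of bright and dark artefact
voxels seen in real leakage.

A fraction of the fluctuation (`leak_fraction_caipi`,
`leak_fraction_grappa`, defaults 0.2) is added at every predicted alias
disk, weighted by a Gaussian radial profile (σ = half the disk radius)
peaked at the disk center — a point-spread-like falloff, which also makes
variance-map local maxima coincide with the injected centers.  I.i.d.
Gaussian noise (default sd 2 a.u., i.e. 2% of the source amplitude) is
added everywhere; Gaussian rather than Rician noise is adequate at this
SNR and keeps the generator simple.  A single integer seed determines the
entire run (fluctuation draw first, then noise).

The default paradigm is 7.5 alternating cycles of 20 s on / 20 s off —
300 s, exactly 200 volumes at TR 1.5 s, ending on a half cycle — and the
default scenario uses the reference geometry (96×96×68, 2 mm voxels, MB4,
GRAPPA 2, PE = y) with the eye at voxel (32, 91, 18).  Tests and the
validation suites run a desk-scale variant: 48×48×16 grid of 4 mm voxels
(same 192 mm FOV and acceleration), eye at the anterior midline
(24, 45, 9), chosen so every simulation finishes in well under a second
while preserving all integer shift relationships (CAIPI 16, GRAPPA 24 of
48).

What passing simulator-based tests shows — and does not.  The generator
validates the geometry pipeline and the statistic's contrast behaviour
(null differences centred on zero under pure noise; injected regions
outranking controls; intensity monotone in leak fraction).  It does not
model k-space reconstruction, coil sensitivities, susceptibility
distortion, physiological noise, drift or head motion, so passing says
nothing about separating leakage from those confounds in real data.

## Numerical and interface choices

- Sample variance uses ddof = 1 throughout.
- A condition with zero usable volume pairs is a hard error naming the
  condition, not a silent NaN.
- CSV outputs use '.' decimals, comma separators, a header row, fixed
  6-significant-digit floats and one leading '#' provenance comment
  (package version, geometry, seed), so repeated runs are byte-identical.
- Label-mask volumes store region i as integer i+1 with a CSV sidecar for
  labels/centers; overlapping masks resolve first-wins with a warning.
- CLI exit codes: 0 success, 1 user error, 2 internal error.

## Known limitations

- Oblique/tilted slice prescriptions are not modelled; the geometry is a
  rectilinear voxel grid.
- The alias model assumes the standard contiguous-stride slice grouping;
  sequences with custom slice ordering need their own grouping rule.
- Artefact *sources* are not detected automatically; the user supplies
  the source voxel (e.g. the eye) and, for control placement, a brain
  mask.
- The m = 1…M indexing makes some positions coincide when M is a
  multiple of the CAIPI denominator; coincident positions are flagged,
  and downstream statistics treat them as ordinary regions.
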