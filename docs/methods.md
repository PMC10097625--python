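# Methods

`tractoprof` implements the computational core of ROI-based tractometry: it
takes a whole-brain tractogram and a set of binary ROIs in a common native
space, carves out tracts, forces them into compact bundles, summarises a
voxelwise metric along each bundle as a 100-node profile, and quantifies the
agreement between two reconstructions of the same tract. Every stage is
deterministic: the same inputs and parameters produce byte-identical
outputs, which is the property the agreement metrics are designed to
measure.

## Spatial conventions

All geometry lives in world-space RAS millimetres. A `VolumeGrid` couples an
integer shape to an invertible 4×4 voxel-to-world affine; voxel indices are
0-based and a world point belongs to the voxel whose centre is nearest
(rounding each continuous voxel coordinate to the nearest integer). On
reading NIfTI, the affine is the sform when its code is positive, else the
qform, else a scaled identity from the header zooms. Tractograms use the
MRtrix `.tck` container (little-endian 32-bit floats on write, either byte
order on read; NaN triples delimit streamlines, an Inf triple ends the
file), and gradient tables use the FSL bvec/bval text layout. Grids are
never resampled implicitly: any mismatch between the frames of two inputs
is an error, since in this workflow a mismatch almost always means an
upstream registration problem.

## Streamline–voxel membership

Selection, mask export and ROI clipping all reduce to the set of voxels a
streamline visits. Under the voxel-centre convention each voxel owns an
axis-aligned box bounded by half-integer continuous voxel coordinates, so
the visited set is computed exactly: each polyline segment is split at its
crossings of the half-integer planes and the midpoint of every sub-interval
is rounded. Exact traversal was preferred over densified sampling because
sampling at any finite step misses short corner clips (at half-voxel
spacing, roughly 10% of the voxels found by a 0.01 mm dense-sampling oracle
on jagged test polylines); the traversal is a superset of any dense
sampling and agrees with a 0.001 mm oracle exactly on the test geometry.

## Diffusion tensor metrics

The tensor model `S = S0·exp(−b gᵀDg)` is fitted voxelwise by two-pass
weighted least squares on log-signals: an OLS pass, then one reweighted
solve with the squared predicted signals as weights (log-transform error
propagation makes the log-signal variance proportional to 1/S²). The
estimator is deterministic and recovers planted tensors from noiseless
signals to ~1e-12 relative. Fitting needs at least one b=0 baseline and six
non-collinear directions; voxels with non-positive signals are flagged NaN
rather than aborting a batch. Both shells of a multi-shell acquisition
enter one fit by default, with a `max_b` switch to restrict to the low-b
shell. For the scalar maps, eigenvalues are clamped at zero (metrics only —
raw tensors are kept for diagnostics): MD = (λ₁+λ₂+λ₃)/3, AD = λ₁,
RD = (λ₂+λ₃)/2, FA = √(3/2)·‖λ−MD·1‖/‖λ‖, with FA of the zero tensor
defined as 0.

## ROI operations

Dilation uses a full 3×3×3 (26-connected) structuring element per
iteration — the common way to push gray-matter ROIs into adjacent white
matter so streamlines can terminate inside them. Combination defaults to
voxelwise union (the operation that grows ROIs out of existing ones), with
an intersection mode available. Validation requires a nonempty mask on the
reference grid.

## Selection and cleaning

`select_by_rois` keeps the streamlines whose voxel sets intersect every
(mode `all`) or any (mode `any`) ROI, preserving input order; an empty
result is an explicit empty-tract value carrying counts, not an exception,
so batch runs can record it and continue.

Cleaning forces a bundle to be compact by iterating: recompute streamline
lengths, the core fiber, and each streamline's distance to the core (mean
over the 100 aligned nodes of Euclidean node distance), then drop
streamlines with `|length − mean| > max_len_sd·SD` (two-sided) or
`distance > mean + max_dist_sd·SD` (one-sided — sitting close to the core
is never anomalous). Standard deviations are population SDs (ddof = 0); a
zero SD disables that criterion for the iteration. Iteration stops when
nothing is removed, when fewer than three streamlines would remain, or
after `max_iter` rounds. Defaults are `max_len_sd = 4`, `max_dist_sd = 4`,
`max_iter = 5`; all three are recorded in the run manifest. At 4 SD the
planted test outliers (a 10× length copy, a 50 mm parallel offset) sit at
z ≈ 4.5 in a 21-streamline bundle and are removed in the first iteration
while every in-bundle streamline survives.

## Super fiber and tract profiles

Profiles need node j to mean the same position along every streamline, so
the bundle is first oriented consistently: the reference streamline is the
one whose centroid is the medoid of all centroids (ties broken by input
order — deterministic and robust to input shuffling), and every other
streamline is reversed iff reversal reduces its summed squared node
distance to the reference. Each streamline is then resampled to N = 100
equal arc-length nodes by linear interpolation. The core fiber ("super
fiber") is the pointwise mean across streamlines at each node; its per-node
dispersion is the SD of the streamline-to-core node distances.

The profile value at node j combines the metric sampled (trilinear
interpolation) at every streamline's node j, weighted by Gaussian distance
to the core node: `wᵢ ∝ exp(−dᵢ²/(2σⱼ²))`, normalized per node. σⱼ defaults
to the node dispersion (floored at 0.1 mm) so the kernel tracks the local
bundle spread; a fixed σ can be supplied. Distances are Euclidean; a
covariance-scaled (Mahalanobis) weighting was considered and rejected as
harder to reason about on anisotropic bundles with no clear benefit at this
scale. Nodes sampling outside the map (or on NaN-masked voxels) are
excluded from the combination; a node with no finite sample is NaN, and an
all-NaN profile is an error. The profile mean (e.g. mean tract FA) is the
arithmetic mean of the 100 values.

The clip-to-ROI ("trunk") variant truncates each aligned streamline from
its last point inside the start ROI to its first subsequent point inside
the end ROI, drops streamlines that never visit both in that order, and
recomputes the core on the trunk — the stable segment between the defining
ROIs. Clipping is optional: profiles can cover the whole tract or only the
trunk.

Per-metric CSVs hold one column per tract and exactly 100 data rows, with
`NA` for missing values.

## Agreement metrics

Between two reconstructions of one tract:

- **Dice** `2|A∩B|/(|A|+|B|)` on the binary masks.
- **Density correlation**: Pearson correlation of per-voxel streamline
  counts over the *union* of the two supports. The whole grid would inflate
  the correlation through shared zeros; the intersection would discard
  exactly the disagreement being measured.
- **Bundle adjacency**: over voxels of A not in B, the mean world-space
  distance to the nearest voxel centre of B; symmetrically for B∖A; the
  reported value is the mean of the two directional means (0 for identical
  masks). This reads "average distance of disagreement" literally and makes
  toy cases exactly computable.
- **Profile correlation**: Pearson correlation of the two 100-node
  profiles.

Undefined statistics (zero variance, empty masks) raise a typed error at
the function level and surface as explicit flags in the aggregate report —
never as silently propagated NaN.

## Synthetic phantom

The phantom generates the study conditions used throughout the tests and
the reproducibility analysis: a circular-arc centerline (radius 30 mm,
~80° of arc) inside a 40×40×40 voxel grid at 1 mm isotropic; a bundle of
200 streamlines whose offsets are white Gaussian noise smoothed along arc
with a 10 mm correlation length and rescaled to an exact 1 mm per-node SD
(so streamlines stay smooth rather than jagged); each streamline reversed
with probability ½ to exercise orientation alignment; an FA-like scalar
field equal to a chosen function of arc position inside a 5 mm tube around
the centerline; spherical defining ROIs centred on the centerline; and DWI
signals `S0·exp(−b gᵀDg)` from planted tensors on a two-shell scheme (1 b=0
plus 10 directions each at b = 1000 and 2000 s/mm², quasi-uniform
Fibonacci-sphere directions), with optional additive Gaussian noise. Every
generator is a deterministic function of its seed, bitwise on serialized
output.

What the phantom does *not* emulate: crossing fibers, partial-volume
averaging at bundle edges, Rician noise floors, susceptibility distortion,
or anatomically realistic tract shapes. Passing tests therefore demonstrate
the correctness and determinism of the computations, not the anatomical
validity of tract reconstructions on acquired data.

## Pipeline driver and provenance

`run_pipeline` executes, per tract row of the parameter table: resolve ROIs
(union extra ROIs, dilate) → validate → select → clean → optional
clip-to-ROI → core fiber → per-metric profiles → export (`<tract>.tck`,
`<tract>_SF.tck` for the super fiber, `<tract>_fa_bin.nii.gz` binary mask,
`<tract>_fbcnt.nii.gz` fiber-count mask, `<metric>_profiles.csv`). A
failure in one tract is recorded and does not abort the others; an empty
selection is an outcome, not an error. The manifest records SHA-256 digests
of file inputs, the fully resolved parameter set for every tract, the
package version, a timestamp and per-stage streamline counts; apart from
the timestamp, repeated runs produce byte-identical outputs. Execution is
single-threaded on purpose — multi-threaded reductions reorder floating
point operations and break bit-level reproducibility.

## Problem sizes

The reference analyses use the 200-streamline phantom on the 40³ grid;
unit tests use smaller bundles (5–60 streamlines) and 10³–20³ grids. These
sizes were chosen so the whole suite and the reproducibility analysis run
comfortably on a single core while keeping the planted-statistics tests
(CLT bounds, SD recovery within 15%) well-powered.

## Known limitations

- The tensor fit is plain WLS; no RESTORE-style robust reweighting, no
  constrained positive-definiteness.
- Orientation alignment is pairwise against a single reference; bundles
  with genuinely ambiguous geometry (e.g. closed loops) may align
  arbitrarily (deterministically, but not meaningfully).
- Bundle adjacency is defined between voxelized masks, so its resolution is
  bounded by the voxel size.
- Streamline generation itself (tracking) is out of scope; the package
  starts from an existing whole-brain tractogram.
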