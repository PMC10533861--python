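# Methods

This note documents the models, parameters, and design choices behind
`aneucad`: a cerebral-aneurysm CAD pipeline (vessel thresholding →
isovoxel resampling → Hessian keypoints → patch scoring → cutoff
filtering → clustering → candidates) plus the reader-study evaluation
layer that quantifies a score-cutoff change, and the synthetic data that
stands in for clinical TOF-MRA.

## Coordinate and intensity conventions

Voxel indices are 0-based; world position = origin + (index + 0.5) ·
spacing (voxel-center convention); all distances are in mm.  Intensities
are arbitrary units; the phantom uses 1000 (vessel) over 100
(background), roughly the bright-blood contrast regime of TOF-MRA.

## Synthetic phantoms

Vessels are random-walk polylines (step ≈ ¼ of the smallest grid extent,
direction perturbed each step, reflected at a safety margin from the
walls) rendered as constant-radius tubes by exact point-to-segment
distance.  Aneurysms are spheres tangent to a randomly chosen centerline
point, displaced perpendicular to the local tangent so the bulge
protrudes from the wall; the config requires aneurysm radii ≥ the
smallest vessel radius so bulges are geometrically distinguishable from
tubes.  Noise is additive i.i.d. Gaussian — adequate to exercise
thresholding and keypoint stability, but *not* MR physics: no flow
artifacts, no intra-aneurysmal signal loss, no Circle-of-Willis anatomy.
Defaults (64×64×32 voxels at 0.5×0.5×1.0 mm; vessels 1.0–1.5 mm radius;
aneurysms 2–3 mm; noise SD 45 = 5 % of contrast) approximate a cropped
1.5 T acquisition at desk scale.  Requested geometry that cannot be
placed raises `PlacementError`; nothing is silently truncated.  All
randomness flows through one `numpy` generator seeded from the config.

## Synthetic cohorts

Each case draws a physician category (none / suspicion / definite) from
configured prevalences (defaults 2 % definite, 8.4 % suspicion, the
regime of a large screening program).  Every positive case carries
exactly one true lesion, detected with probability `p_det` (detected →
one TP candidate, missed → one FN); per-case FP counts are
Poisson(`fp_rate_per_case`).  The Poisson choice is an assumption of this
module — per-case FP distributions of deployed detectors are not
published.  Candidate scores are uniform on configurable ranges (default
[0.5, 1.0] for both classes) so top-k truncation reorders candidates
nontrivially.  Both detector rates accept per-threshold mappings so one
config describes both operating points of a tuning comparison.  What
passing tests on these cohorts show is that the *evaluation* layer is
correct and well-calibrated (parameter recovery within sampling error);
they say nothing about any real detector's accuracy.

## Vessel extraction and resampling

Otsu's method (default) or a percentile threshold; the mask is
`intensity ≥ threshold` and the threshold is logged, since cutoff
behavior on large-voxel acquisitions is exactly the kind of thing one
audits.  A constant-intensity volume yields an empty mask with a warning
rather than an error.  Resampling uses trilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1, nearest padding) onto an
isotropic grid at the smallest input spacing by default — upsampling the
thick axis rather than discarding in-plane resolution.  An
already-isotropic volume at the target spacing is returned unchanged.
In the full pipeline the threshold is computed once on the native volume
and re-applied to the resampled intensities, keeping the mask and the
resampled grid consistent.

## Keypoint detection

The volume is Gaussian-smoothed at a scale of 1.0 mm (≈ the smallest
vessel radius; below it, noise dominates the Hessian; above ~2 mm,
small bulges blur into their parent vessel), then rescaled to [0, 1] so
curvature magnitudes are comparable across intensity scales.  The
Hessian is assembled from repeated `numpy.gradient` calls (spacing-aware
central differences, symmetrized) and its eigenvalues are computed per
masked voxel.  Blob-ness at a voxel is min|λ| if all three eigenvalues
are negative, else 0; keypoints are voxels above the curvature cutoff
(default 10⁻⁴ per mm², chosen low so that selectivity is delegated to
the classifier stage, as in a high-sensitivity candidate generator) that
are local maxima of blob-ness in their 3×3×3 neighborhood.  On grids up
to ~32³ the detector is verified against an independent per-voxel
eigen-decomposition with explicit loops.

## Patch extraction and scorers

Patches are 5 consecutive axial slices of 24×24 pixels centered on the
keypoint (the slicing plane is configurable in principle; axial is the
default because screening acquisitions are axial).  Out-of-grid voxels
are zero-filled; intensities are min–max normalized to [0, 1] per patch,
with zero-range patches mapping to all-zeros.

Two interchangeable scorers implement the `Scorer` protocol:

* **Residual network** (`aneucad.nnet`) — a 2D CNN treating the five
  slices as input channels: 1 stem convolution, 18 two-convolution basic
  blocks in three stages (spatial sizes 24→12→6), 1×1 projection
  shortcuts at the two width transitions (39 convolutions total), batch
  normalization everywhere, global average pooling, one fully connected
  unit, sigmoid output.  Channel widths default to 8/16/32 — desk scale;
  the census, not the capacity, is the contract.  Training is binary
  cross-entropy under Nesterov-Adam (Nadam) with the classic
  hyperparameters (lr 0.002, β₁ 0.9, β₂ 0.999, ε 10⁻⁸, schedule decay
  0.004, with the momentum warm-up schedule μ_t = β₁(1 − ½·0.96^(t·sd))),
  a seeded stratified 80/20 train/validation split, and two profiles:
  `DESK_PROFILE` (20 epochs, batch 32) and `FULL_PROFILE` (100 epochs, the deployed schedule).
  Everything is numpy with manual backpropagation (convolutions as 9
  shifted channel-mixing matmuls), float32, bit-reproducible for a fixed
  seed on one machine; gradients are spot-checked against finite
  differences in the suite.  The loss choice and split are our own
  decisions; the output range forces the final sigmoid.

* **Rule scorer** (`aneucad.scorer.RuleScorer`) — a deterministic
  geometric score used wherever training noise would obscure what a test
  measures.  It binarizes each slice at 0.5 (after a 3×3 median filter),
  takes the Euclidean distance transform of the bright mask, and reads
  the largest center-window value minus half a pixel: the radius of the
  widest fully-bright disc around the keypoint.  A bulge is fat
  (radius ≥ 2 mm by construction); any tube — including the parent
  vessel that accompanies every real bulge — is thin (≤ 1.5 mm).  The
  logistic map `1/(1+exp(−12·(r − 1.55)))` places bulges ≥ 0.9 and pure
  tubes ≤ 0.1 under the default phantom geometry.  Vessel junctions and
  tight bends can read fat and score mid-range — realistic false
  positives that make cutoff tuning meaningful.

## Postprocessing

Filtering keeps keypoints with score ≥ θ (inclusive, so θ = 1.0 remains
meaningful).  Clustering is single-linkage: connected components of the
graph joining keypoints within 5 mm (about one aneurysm diameter; an
exact brute-force oracle exists, which is why this simplest scheme was
chosen over density-based alternatives).  Each cluster becomes one
candidate at the unweighted mean of member positions ("center of
gravity" — no score weighting) with the max member score (mean available
as an option).  Top-k limiting sorts by score with deterministic
tie-breaks (larger cluster first, then lexicographic position) so
`limit(k)` is always a prefix of `limit(k+1)`.  Because filtering
precedes clustering, raising θ can both remove whole candidates and
sharpen surviving centroids; cluster *count* is not monotone in θ
(removing a bridge keypoint can split a cluster), so monotonicity is
asserted at the keypoint level only.

## Evaluation conventions

* Physician-positive = suspicion or definite (a suspicion reading cannot
  be ruled out and is counted positive everywhere).
* Contingency tables pair that with *case-level detector output
  presence*: a case is AI-positive iff the detector emitted ≥ 1
  candidate of any label.  Sensitivity = 100·a/(a+b), displayed to one
  decimal; FPs/case = total FPs / total cases (FPs in positive cases
  included), displayed to two decimals; p-values to three.
* FROC sensitivity is TP-based: after truncating each case to its top k
  candidates by score, a positive case counts as detected only if a TP
  candidate survives.  The presence-based rule would credit a case whose
  candidates all missed the lesion, which is meaningless for a curve
  meant to show detection vs FP burden; top-k nesting makes both FROC
  coordinates non-decreasing in k.
* Matching: a candidate hits a lesion if within max(5 mm, lesion radius)
  of its center; a lesion is detected if ≥ 1 candidate hits it.
* Tests: pooled-variance two-proportion z-test (two-sided), pooled
  Student's t-test, Pearson chi-square with a caller-visible Yates flag.
  The flag exists because published baseline tables are numerically
  consistent with different conventions: the full-cohort sex comparison
  reproduces (p = 0.443) only with correction, the feedback-subset one
  (p = 0.009) only without.  For the secondary sensitivity comparison
  (163/165 vs 106/112) the pooled z-test gives p ≈ 0.043 where the
  source prints 0.05; the exact variant used there is unknown, and this
  package reports its computed value rather than forcing agreement.
  Degenerate inputs (identical proportions, zero pooled variance) return
  the exact null (statistic 0, p = 1) instead of NaN.

## Problem sizes

Default experiment sizes are chosen for interactive desk use: phantoms of
64×64×32 voxels (a few hundred ms per detection run), 8-phantom
end-to-end comparisons, 5000-case cohorts for parameter recovery, and
500-patch training sets at 20 epochs for the learning check.  All scale
linearly if larger studies are wanted.

## Known limitations

The phantom's geometric separability makes the rule scorer nearly
perfect; real TOF-MRA false positives (flow artifacts, venous
structures, bone interfaces) are absent, so absolute sensitivities and
FP rates here do not transfer to clinical data — only the machinery and
its invariants do.  The network's clinical accuracy is out of scope by
design: weights of the deployed detector are unavailable, and the
package validates the architecture census, the training contract and
learnability on separable data instead.  FROC curves use at most the
k ≤ 5 operating points of candidate limiting, not score sweeps; JAFROC
and alternative figures of merit are not implemented.
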