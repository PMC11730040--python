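# Methods

This note documents the models, conventions and numerical choices behind
`cmbchar`, and what the synthetic phantom does and does not establish about
behaviour on real data.

## Volumes and orientation

All volumes are NIfTI-1, handled through nibabel. On load, every volume is
reoriented to the closest canonical RAS+ axis order (the MNI convention) by
axis permutation and flips derived from the affine — the effect of the usual
`fslreorient2std` preprocessing, reproduced in-memory so that masks and
atlases always meet in one coordinate convention. The reorientation updates
the affine consistently, so world coordinates of voxel centres are preserved
exactly and the operation is idempotent. Voxel dimensions come from the
header zooms; indices are 0-based; bounding boxes are half-open `[lo, hi)`.

Probabilistic atlases appear in the wild encoded either 0–1 or as percent
0–100. The encoding is detected from the data maximum (> 1.5 ⇒ percent) and
stored as a `scale` attribute; thresholds are always *stated* in percent and
mapped onto the stored scale, which makes threshold values like 50 and 60
unambiguous regardless of the source file.

## Lesion size

A lesion is a maximal connected set of foreground voxels; connectivity
defaults to 26 (faces + edges + corners) because CMBs are compact blobs and
6-connectivity would split diagonal digitisation artefacts into spurious
lesions. The flag is exposed (6/18/26) for sensitivity analyses.

The diameter is defined through moment matching: the lesion is replaced by
the uniform-density solid ellipsoid with the same second-order central
moments (same spread and orientation), and the reported diameter is that
ellipsoid's major-axis length in mm. Since a solid ellipsoid of semi-axis
`a` has central second moment `a²/5`, the estimator is `2·sqrt(5·λmax)` with
`λmax` the largest eigenvalue of the covariance of voxel-centre coordinates.
Two conventions matter:

* **mm-space moments.** For anisotropic voxels, indices are scaled per axis
  by the voxel dimensions *before* the covariance is formed, rather than
  computing voxel-space moments and applying a single scale factor. The two
  agree on isotropic grids.
* **Per-voxel self-extent.** Each voxel contributes `d_a²/20` per axis to
  the covariance diagonal — the central second moment of a solid ball of
  diameter `d_a`. This choice is self-consistent with the ellipsoid model:
  a single voxel reports a diameter of exactly one voxel, rather than zero
  (no correction) or 1.29 voxels (the uniform-cube moment `d²/12`, which
  measures the cube's *matched ellipsoid*, systematically oversizing small
  lesions). Diameters are additionally floored at `max(voxel_dims)`.

On digitised solid balls of radius 2–8 voxels the estimator recovers the
continuous diameter within one voxel on isotropic and anisotropic grids
(test-covered); the residual error is quantisation, largest for the smallest
balls. Because near-spherical digitisations at the 6-voxel scale carry a few
percent of moment bias, the worked-example calibration lesion is a digitised
*prolate* spheroid (nominal semi-axes 3.0 × 2.25 × 2.25 voxels, minor/major
aspect 0.75): its clear principal direction makes the measured moment axis
equal the nominal 6-voxel axis to ~0.5%, so the pipeline reports 5.4 mm on a
0.9 mm grid at the tool's 1-decimal output precision.

Diameters above 10 mm (the upper end of the CMB definition) are flagged in
reports but not removed; inclusion policy belongs to the caller.

## MARS atlas assembly

The thirteen structures and their region membership are fixed: brainstem and
cerebellum (infratentorial); basal ganglia, thalamus, internal/external
capsules, corpus callosum and deep white matter (deep); frontal, parietal,
temporal, occipital lobes and insula (lobar). The default lookup table binds
them to their conventional sources (Harvard-Oxford subcortical with
thresholds 50/60, MNI structural, JHU ICBM-DTI-81 labels); discrete sources
take no threshold, and a user-supplied LUT CSV can rebind sources,
thresholds, dilation flags and codes freely.

Assembly decisions, where the procedure is genuinely open:

* **Inclusive thresholding** (`p ≥ t`): keeps the boundary voxels of a
  uniform-probability structure, the common atlas-tool convention.
* **Dilation element**: "size 3" is read as the element's width, so the
  default is a 3×3×3 cube; ball and cross elements are selectable. Only
  masks flagged `dilate` (the cortical lobes) are dilated — the dilation
  exists to pull the grey–white junction into the lobar region.
* **White-matter carve-out**: internal/external capsules and corpus
  callosum are removed from the deep white matter mask because they are
  rated as separate structures.
* **Overlap priority**: infratentorial > named deep structures > deep white
  matter > dilated lobar > background. Rationale: lobar dilation is meant to
  extend cortex outward, not to annex deep or infratentorial tissue, and
  boundary voxels near the tentorium are the canonical misclassification
  risk. Within one priority tier, a contested voxel goes to the structure
  whose *undilated* mask is nearest (Euclidean distance in mm); exact ties
  go to the lower structure code, making assembly deterministic.

Every voxel receives exactly one label; label 0 is background/unclassified.

* **Subject-space transform**: the supplied 4×4 matrix maps template world
  coordinates to subject world coordinates. Each structure mask is pulled
  through the inverse map with trilinear interpolation and thresholded at
  0.5, then the masks are re-merged under the same priority rules (without
  re-dilating — lobes were already extended in template space). A converter
  for the FSL FLIRT scaled-voxel matrix dialect (including the x-flip for
  positive-determinant images) is provided; estimating registrations is out
  of scope.

## Rating

Each lesion is assigned by rounding its centroid (half-away-from-zero) to a
voxel index and reading the atlas label there; rounding happens in voxel
coordinates because the lookup is voxelwise. Centroids on label 0 or outside
the grid are reported as *unclassified* rather than dropped or force-assigned
— silent reassignment would corrupt the MARS counts. A majority-vote mode
(most frequent label over the lesion's voxels) is available for
boundary-straddling lesions, whose centroids can shift into adjacent
structures under segmentation error. Region counts are pure sums of member
structure counts; `total = Σ structure counts + unclassified` always holds
and is validated on every rating. Left/right lateralisation is not modelled
(ratings aggregate bilaterally), but a lateralised LUT works without code
changes.

## Evaluation

Predicted and reference lesions are paired one-to-one, greedily by
descending voxel overlap (≥ 1 voxel required), ties broken by centroid
distance then lower id; a centroid-distance criterion (≤ 5 mm) is available
for masks that abut without overlap. On compact, well-separated lesions the
greedy pairing attains the exhaustive optimum (test-covered by brute force on
instances with ≤ 6 lesions per side).

Region metrics are lesion-level: a matched lesion is a true positive of
region R when both ratings place it in R, a false negative of R when only
the manual rating does, a false positive of R when only the automated rating
does. Unmatched reference lesions count as false negatives of their manual
region; unmatched predictions enter precision through their automated region
only, since they have no manual rating. Overall accuracy is the fraction of
matched lesions with identical region labels. A count-level mode
(`TP_R = min(pred, ref)` per region) supports references that provide MARS
subscores without masks. Confusion matrices (manual rows, automated columns)
are restricted to matched lesions, so metrics recomputed from the region
matrix reproduce the per-region values — an internal consistency check the
suite enforces. Reports round metrics to 2 decimals and sizes to 1 decimal,
and the size-error summary quotes integer percentages of lesions below 1 mm
and above 6 mm error.

## Synthetic phantom

The phantom emulates the *geometry* of the problem, not its physics: thirteen
disjoint primitives (boxes, one ball) on a 64³ grid at 0.9 mm isotropic — a
common SWI resolution — stand in for the structures; lesions are digitised
balls of 1–12 mm placed at chosen voxel positions; probability maps are 100
inside a primitive with a linear two-voxel falloff, so binarising at 50
recovers the primitive within a one-voxel shell. The default lesion set
plants one lesion per structure (2.7–5.4 mm, at least two voxels inside the
structure). Degradations emulate segmentation failure modes: `jitter`
(Gaussian mm displacement, rounded to voxels), `drop` (each lesion removed
with probability p — false negatives), `split_merge` (random erosion or
dilation — size errors). All randomness flows through one seeded generator;
identical seeds give bitwise-identical masks.

What phantom-based tests show: the pipeline's bookkeeping is exact (label
partitions, count conservation, determinism), sizing is within quantisation
error, assignment is perfect for interior lesions, and the evaluation is
calibrated (drop(p = 0.3) over 200 seeded phantoms yields a false-negative
fraction within three binomial standard errors of 0.3). What they do not
show: behaviour under real registration error, anatomy-shaped structures
with thin interdigitated boundaries, vessel-fragment artefacts, or
rater-level ambiguity between "definite" and "possible" CMBs — the phantom
has no intensities and its structures are convex and well separated, so
boundary misassignment rates on real data will be higher than the phantom's
zero.

## Problem sizes

Default test and acceptance runs use 64³ grids (13 structures, 13–17
lesions), spheres up to radius 8 voxels, 200 seeded degradations for the
calibration check, and brute-force matcher verification up to 6 lesions per
side — sizes at which every property is checked exhaustively while the whole
suite runs in seconds.

## Known limitations

* Structure assignment is centroid-based by default; lesions straddling a
  boundary can flip structures with sub-voxel centroid shifts (the suite
  documents this sensitivity). Majority-vote mode mitigates but does not
  eliminate it.
* The moment diameter assumes an ellipsoidal lesion; for markedly
  non-convex shapes (vessel fragments) it reports the spread of the whole
  component, which can exceed any single lobe of the shape.
* Probabilistic-atlas scale detection by data maximum misreads a percent
  atlas whose global maximum is ≤ 1.5 (an almost-empty structure); supply a
  0–1 encoded file or set the scale explicitly in that case.
* The affine transform supports linear (12-dof) registration only, applied,
  never estimated.
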