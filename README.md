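# cmbchar

Automated characterisation of cerebral microbleeds (CMBs) from binary lesion
masks: per-lesion **size** and anatomical **location** under the Microbleed
Anatomical Rating Scale (MARS).

CMBs are small (2–10 mm) round hemosiderin deposits visible as hypointense
foci on susceptibility-weighted MRI, and an important biomarker of cerebral
small vessel disease. Automated segmentation methods produce binary CMB maps;
to be clinically useful those maps must be turned into metrics — lesion
count, diameter, and distribution over the MARS regions (*infratentorial*,
*deep*, *lobar*) and their thirteen structures. `cmbchar` performs that step:
it takes a binary NIfTI mask, extracts connected lesions, sizes each one, and
fills in the MARS form automatically. It is aimed at neuroimaging researchers
running CMB studies at cohort scale, and at developers evaluating CMB
segmentation algorithms region by region.

## Method

**Size.** Each 26-connected lesion is measured as the major-axis length of
the uniform solid ellipsoid with the same second-order central moments as the
lesion's voxel set. With voxel coordinates scaled to mm and central
covariance matrix Σ (plus a per-voxel self-extent term d²ₐ/20 on the
diagonal), the diameter is

```
D = 2 · sqrt(5 · λ_max(Σ))            [mm]
```

since a solid ellipsoid of semi-axis *a* has central second moment *a*²/5
along that axis. A lesion spanning 6 voxels along its major axis on a
0.9 mm isotropic grid therefore has D = 6 × 0.9 = 5.4 mm. Diameters are
floored at one voxel and lesions above 10 mm are flagged, not dropped.

**Location.** A MARS structure label atlas is assembled from per-structure
masks (probabilistic sources binarised at a percent threshold, e.g. 50 for
the Harvard-Oxford subcortical structures, 60 for deep white matter):
cortical lobe masks are dilated (3×3×3 element) to cover the grey–white
junction, the capsules and corpus callosum are carved out of the deep white
matter mask, and overlaps are resolved by a fixed priority (infratentorial >
named deep structures > deep white matter > lobar). The atlas is carried into
subject space through a supplied 4×4 affine (trilinear resampling of each
structure mask, threshold 0.5). Each lesion is then assigned to the structure
at its rounded centroid — the per-axis mean of its voxel coordinates — and
counts are aggregated per structure and per region.

**Evaluation.** Against a manual reference, lesions are matched one-to-one by
voxel overlap (greedy, largest first); the package reports per-lesion
absolute size errors and their mean, per-region sensitivity / precision / F1
(F1 = 2·s·p/(s+p)), overall accuracy, structure- and region-wise confusion
matrices, and false-negative histograms. A synthetic phantom module generates
every input needed for end-to-end testing — no data download required.

## Worked example

Generate a 64³ phantom (13 structures, one lesion each, a degraded
"predicted" mask with lesions dropped at rate 0.3), then size, rate and
evaluate it:

```sh
cmbchar phantom --out-dir demo --seed 1 --perturb drop:0.3
cmbchar size --mask demo/lesions.nii.gz --out demo/sizes.csv
cmbchar rate --mask demo/lesions.nii.gz --atlas demo/atlas_labels.nii.gz \
             --lut demo/atlas_lut.csv --out demo/rating.json
cmbchar eval --pred-mask demo/lesions_predicted.nii.gz \
             --ref-mask demo/lesions.nii.gz \
             --atlas demo/atlas_labels.nii.gz --lut demo/atlas_lut.csv \
             --out demo/eval.json
```

`sizes.csv` holds one row per lesion (a 3.6 mm phantom lesion is measured as
3.68 mm — quantisation on a 0.9 mm grid). `rating.json` is the filled MARS
form:

```
region_counts: {infratentorial: 2, deep: 6, lobar: 5}   total: 13   unclassified: 0
```

i.e. every planted lesion was counted in its intended region. `eval.json`
compares the degraded mask against the original: with seed 1, two lobar
lesions were dropped, so

```
infratentorial: sensitivity 1.00  precision 1.00  f1 1.00
deep:           sensitivity 1.00  precision 1.00  f1 1.00
lobar:          sensitivity 0.60  precision 1.00  f1 0.75
overall accuracy 1.00   size MAE 0.0 mm   TP 11  FP 0  FN 2
```

Sensitivity drops exactly where lesions were removed; matched lesions keep
perfect region agreement and zero size error, as they must for a pure-drop
degradation.

The same operations are available as library functions
(`cmbchar.rate_subject`, `cmbchar.estimate_diameter`,
`cmbchar.evaluate_subject`, ...); see the module docstrings.

## Scope

The package starts from binary masks: CMB segmentation itself, skull
stripping, bias correction and registration *estimation* are upstream
concerns (a supplied affine is applied, never estimated). Third-party atlas
files are not shipped; the phantom module generates structurally equivalent
test atlases, and real MARS atlases can be supplied as NIfTI + LUT CSV.
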