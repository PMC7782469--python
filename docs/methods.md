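# Methods

## Problem and approach

Unstructured brain-MRI exports rarely say what each series *is*: series
descriptions are free text, differ across sites and languages, and are
often missing after anonymization.  `scansorter` identifies the scan type
of each series from voxel appearance alone and uses the result to sort
the dataset.  Eight classes are distinguished: T1w, T1wC (post-gadolinium
T1w), T2w, PDw, T2w-FLAIR, DWI, PWI-DSC and derived parametric maps
(ADC/FA/CBV-style images).  The class order is frozen and persisted with
every model artifact.

The classifier is deliberately slice-level and 2-D: every scan is reduced
to 25 standardized slices, each classified independently, and the scan
label is the majority vote of the 25 slice predictions.  A scan-level
binary feature records whether the source series was 4-D (multi-b-value
DWI or a DSC time series), since that fact is informative but is
discarded when the first 3-D element is extracted.

## Preprocessing

1. **4-D reduction.**  A rank-4 series contributes only its first
   temporal element; a binary 4-D label (1 iff the input had rank 4 —
   dimensionality, not temporal extent, decides) accompanies all its
   slices.
2. **Reorientation.**  Axes are permuted/flipped — never interpolated —
   to RAS order, using the affine built from the DICOM direction cosines
   (tag 0020,0037) or the NIfTI header.  Affines with shear above 1e-3
   are replaced by their nearest orthogonal factor (polar decomposition,
   computed via SVD) with a warning.
3. **Fixed-grid resampling** to 256x256x25 voxels with cubic b-spline
   interpolation, preserving the physical field of view: the output
   spacing along each axis is `extent / size`.  Sample `j` along an axis
   sits at input index `(j + 0.5) * n_in / n_out - 0.5`, which makes
   identity resampling exact and conserves `size x spacing` to
   round-off.  Because the target grid is axis-aligned the tensor-product
   spline is evaluated separably (one small weight-matrix product per
   axis over prefiltered coefficients); out-of-support positions are
   clamped to the edge sample, and spline coefficients are extended by
   edge replication.  Near the volume boundary this edge policy perturbs
   values with a decay of ~0.27 per input voxel — tests of closed-form
   cases therefore assert on the interior.
4. **Slice split and scaling.**  The 25 planes along the
   inferior–superior axis are scaled independently to min 0 / max 1.  A
   constant slice (the formula is undefined there) maps to all zeros, a
   class-neutral value.  No augmentation is applied.

The slice ordering question (native header order vs. anatomical order) is
resolved by always splitting after reorientation, so slices run
inferior to superior.

## Network and training

A VGG-style stack: blocks of `n x (3x3 conv -> batch norm -> PReLU)`
followed by 2x2 max pooling; flattened features plus the concatenated
4-D label feed dense layers and an 8-way softmax.  The default
configuration is blocks (32,2)(64,2)(128,2)(256,2) with one 512-wide
hidden dense layer; where the 4-D label enters is configurable, with
late fusion before the first dense layer as the default (it preserves
the convolutional stage's purity and needs no spatial broadcasting).
The layers, Adam, and guided backpropagation are implemented in NumPy
with hand-derived backward passes; this keeps the package dependency-light
and every computation deterministic for a given seed (verified against
finite differences in the test suite).

Training follows a fixed protocol: cross-entropy loss, Glorot-uniform
initialization, Adam with learning rate 1e-3, beta1 0.9, beta2 0.999,
batch size 32, at most 100 epochs.  The learning rate divides by 10
(floor 1e-7) when the last 3 epochs never beat the best training loss
seen before them, and training stops early after 6 such epochs.  Both
rules are pure functions of the recorded loss history — no hidden
cooldown state — so a run can be audited by replaying its history file.
A consequence of statelessness is that a long plateau can trigger
reductions on consecutive epochs; with patience 3 and factor 10 the rate
reaches its floor quickly once learning truly stalls, which is the
intended behaviour.  "No improvement" means not strictly below the
running best of the *training* loss; no validation split is consulted.

PReLU slopes start at 0.25; batch-norm uses eps 1e-5 and running-stat
momentum 0.9.  Hidden dense layers use PReLU without batch norm.  Ties
inside a max-pooling window share the gradient equally.

The **reduced configuration** used for desk-scale work keeps the same
topology at 1/16 the resolution: an average-pool downsampling layer
(factor 4) in front of blocks (8,1)(16,1) and a 32-wide dense layer.
Saliency maps remain input-sized because the pool layer participates in
backpropagation.

## Aggregation, orientation, metrics

Per-slice argmaxes are tallied; the class with the most votes wins.  The
tie chain (never observable with 25 slices and a clear winner, but
required for determinism) is: highest mean probability over the tied
classes, then lowest class index; `tie_broken` records when it fired.

Spatial orientation comes from the direction cosines: the slice normal
(row x column) has its largest absolute component along x (sagittal),
y (coronal) or z (axial).  Cosines cannot distinguish a 3-D acquisition
from a stack of 2-D slices, so "3D" is taken from MRAcquisitionType
(0018,0023) when present — a documented sharpening of the
cosines-only rule.

Overall accuracy is correct scans / total scans; per-class accuracy
restricts the denominator to one true class; the 8x8 confusion matrix has
truth in rows.  A per-slice accuracy (before the vote) is also computed;
on every dataset we generate it is at or below the scan-level accuracy,
since extreme slices often contain too little brain to classify.

## Sorting

BIDS output (NIfTI): T1w/T2w/PDw to `anat` with the matching suffixes,
T1wC to `anat` with `ce-gd`, T2w-FLAIR to `anat/_FLAIR`, DWI to
`dwi/_dwi`.  DSC perfusion has no finalized core-BIDS home, so it goes
under `perf/` with suffix `_dsc` (a documented extension); derived maps
go to `derivatives/scansorter/` as is idiomatic for non-raw data.
Duplicates within a session get `run-01, run-02, ...` in sorted scan-id
order (stable across runs).  Custom DICOM layouts come from a template
over `{subject} {session} {scan_type} {orientation} {run}`; files are
copied byte-identically.  Plans are built first and inspectable
(dry-run); execution skips byte-identical destinations (idempotent
re-runs) and aborts before touching anything if a destination exists
with different content.

The metadata-heuristic baseline is an ordered first-match rule table
over series/study description keywords, image-type tokens and echo-time
ranges (dual-echo T2/PD resolved by TE < 30 ms vs >= 80 ms).  The
shipped table is an honest compact example of the genre, editable as
JSON — not a reconstruction of any particular site's table.

## Synthetic phantoms

The generator renders a concentric-ellipsoid head: skull/scalp shell,
CSF rim, grey-matter shell, white-matter core, two ventricular CSF
ellipsoids, two anterior eye spheres, and an optional lesion sphere with
an enhancing rim on T1wC.  Geometry is jittered per subject from the
seed; identical specs are byte-identical.  Each scan type assigns its
own mean intensity per tissue (the contrast table), plus Gaussian noise
(default sd 0.03 of the intensity range), Nyquist-style ghosting bands
outside the head for DWI/PWI-DSC/derived, per-b-value attenuation for
4-D DWI, a mid-series bolus dip for DSC time series, and a smooth
low-frequency field for derived maps.

The contrast table is a design fixture.  Values were fixed once under
two constraints: preserve the canonical orderings a radiologist would
name (bright CSF on T2w, suppressed CSF on FLAIR, WM > GM on T1w,
enhancing rim on T1wC, dark CSF with ghosting on DWI), and keep every
pair of classes separable as *distributions* — pairwise two-sample KS
statistic above 0.2 on within-head voxels at the default noise level.
The second constraint matters because marginal histograms are blind to
label swaps (T1w vs T2w differ mostly by a CSF-WM exchange), so
per-class skull/scalp intensities carry much of the separation — which
is also physically reasonable, as scalp fat signal varies strongly
across sequences and enhances after contrast.

Series metadata emulates an unstructured export: randomized folder
names, free-text series descriptions drawn from per-class synonym pools
with a configurable fraction (default 20%) drawn from the *wrong*
class's pool, plausible TR/TE per class, absent TR/TE and a
DERIVED image type for derived maps, and mixed acquisition orientations
including "3D".  A configurable fraction (default 20%) of DWI and
PWI-DSC series is stored 4-D.

What the phantoms do **not** emulate: real anatomy and its variability,
k-space/reconstruction artifacts beyond the ghost bands, motion, bias
fields, partial-brain fields of view, or realistic scanner-dependent
intensity distributions.  Passing the synthetic study therefore shows
that the pipeline's machinery — IO, geometry, preprocessing, training
protocol, voting, sorting — is correct and that the architecture can
learn tissue-contrast signatures; it does not certify any particular
accuracy on clinical data.

## Desk-scale study conditions

The self-contained study (`scansorter.bench.run_study`, also driven by
`scripts/acceptance.py`) uses: 50 subjects x 8 scans = 400 phantoms with
a uniform class mix, noise sd 0.03, 20% misleading descriptions, 20%
4-D fraction; a stratified 75/25 scan split; the reduced model
configuration; and at most 12 training epochs.  These sizes keep the
whole study in the minutes range on a single CPU core while leaving the
task non-trivial (7,500 training slices, 2,500 held-out slices).  The
numbers the study reports — scan-level and per-slice accuracy, the
heuristic baseline's accuracy, orientation accuracy, sorting-integrity
fractions — are computed fresh on every run.

## Known limitations

- Only scalar single-frame DICOM is written/read; enhanced multi-frame
  files, mosaics and vendor-specific scaling quirks are out of scope.
- The eight-class closed world is a hard assumption: an unseen scan type
  (e.g. ASL perfusion) will be forced into one of the eight classes.
- The NumPy network trains small configurations briskly but is not a
  GPU framework; the full 256x256 configuration is provided as the
  faithful architecture description and trains correspondingly slowly.
- Heuristic rules are keyword-based and English-centric, as is typical
  of the genre they emulate.
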