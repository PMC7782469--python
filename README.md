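# scansorter

Scan-type identification and DICOM-to-BIDS sorting for brain MRI.

Large retrospective MRI collections usually arrive as unstructured DICOM
trees whose series descriptions are inconsistent free text ("AX T1 +C",
"t2_flair_tra", "ep2d_diff") or missing entirely after anonymization.
Before any automated analysis can run, somebody has to answer, for every
series: *what kind of scan is this?*  `scansorter` answers that question
from the voxels, not the metadata, and then reorganizes the dataset into
a [BIDS](https://bids.neuroimaging.io/) tree or a user-defined layout.
It is aimed at researchers curating multi-site neuro-oncology or
neuroimaging archives.

## Method

Eight classes are distinguished: `T1w, T1wC, T2w, PDw, T2w-FLAIR, DWI,
PWI-DSC, derived`.  For a scan volume *V* the pipeline computes

1. *4-D reduction*: if *V* is 4-D (multi-b-value DWI, DSC time series),
   keep its first 3-D element and set the binary label d = 1, else d = 0;
2. *reorientation* to canonical RAS axes (permutation/flips only) and
   *resampling* to 256x256x25 voxels with cubic b-spline interpolation,
   preserving the field of view;
3. *slice scaling*: each of the 25 axial slices x_i is mapped to
   (x_i - min) / (max - min);
4. a VGG-style CNN f maps each (x_i, d) to class probabilities
   p_i = softmax(f(x_i, d)) over the 8 classes;
5. the scan label is the **majority vote**
   argmax_c #{ i : argmax p_i = c } over the 25 slices, and the spatial
   orientation (axial / coronal / sagittal / 3D) follows from the DICOM
   direction cosines via the slice normal.

Training uses cross-entropy, Glorot initialization and Adam
(lr 1e-3, beta1 0.9, beta2 0.999, batch 32, <= 100 epochs) with a
plateau schedule (lr / 10 after 3 epochs without a new best training
loss, floor 1e-7) and early stopping (after 6 such epochs).  Guided
backpropagation produces saliency maps of what the network attends to.
A metadata-heuristic baseline (an ordered keyword/echo-time rule table)
and a synthetic phantom generator are included, so the entire pipeline
can be trained, evaluated and demonstrated without any external data.
The CNN and its training loop are implemented in NumPy; see
`docs/methods.md` for the full model description and design rationale.

## Worked example

Generate 64 labelled phantom scans, train a reduced model, predict and
sort — all on a laptop CPU:

```sh
scansorter generate-phantoms --out data --subjects 8 --scans-per-subject 8 --seed 7
scansorter preprocess --input data --work work --manifest data/manifest.tsv
scansorter train --work work --out model.npz --preset reduced --epochs 8 --seed 7
scansorter predict --input data --model model.npz --out predictions.tsv \
    --manifest data/manifest.tsv
scansorter evaluate --predictions predictions.tsv --truth data/manifest.tsv \
    --out metrics.json
scansorter sort --predictions predictions.tsv --manifest data/manifest.tsv \
    --out bids --mode bids --action copy
```

The train step prints

```
trained 8 epochs, final loss 0.3840; model at model.npz
```

and evaluation prints

```
overall accuracy 0.891 over 64 scans; metrics at metrics.json
```

meaning 57 of the 64 phantoms were assigned the correct scan type by
majority vote — a deliberately short 8-epoch run on only 64 scans;
`metrics.json` holds the per-class accuracies and the 8x8 confusion
matrix, and the larger study below reaches a much higher accuracy.  The
`sort` step then materializes a BIDS tree such as

```
bids/sub-008/ses-001/anat/sub-008_ses-001_run-01_T2w.nii.gz
bids/sub-008/ses-001/anat/sub-008_ses-001_run-01_FLAIR.nii.gz
bids/sub-007/ses-001/dwi/sub-007_ses-001_run-01_dwi.nii.gz
bids/derivatives/scansorter/sub-008/ses-001/sub-008_ses-001_desc-derived_map.nii.gz
```

Python API: the same steps are available as functions
(`scansorter.phantoms.generate_dataset`, `scansorter.pipeline.predict_tree`,
`scansorter.classifier.train`, `scansorter.sorter.plan_bids`, ...).

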