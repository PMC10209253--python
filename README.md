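# osteoseg

Automated detection, delineation and quantification of osseous (bone)
lesions from co-acquired FDG-PET/CT volumes, with a statistical validation
module and a synthetic phantom generator so the entire pipeline can be
exercised without patient data.

The pipeline:

1. **I/O & SUV conversion** — read PET/CT DICOM series (self-contained
   explicit-VR codec; no external DICOM dependency), extract the
   radiopharmaceutical factors from the PET header and convert activity
   concentration (Bq/ml) to body-weight SUV; NIfTI read/write with a JSON
   sidecar for units and SUV factors.
2. **Resampling** — bring the CT onto the PET voxel grid with bicubic
   interpolation (physical-coordinate mapping by default; a pure
   matrix-resize compatibility mode is available).
3. **Bone mask** — HU threshold (default 110 HU, capturing marrow and
   cortical bone), Gaussian edge smoothing, per-slice hole filling; the
   mask restricts the SUV map to the skeleton, suppressing physiologic
   uptake (bladder, kidneys, brain, ...).
4. **Lesion segmentation** — absolute SUV threshold (default 3.0) and
   26-connected component labelling; per-lesion volume, SUVmean, SUVmax and
   SUVmax coordinates.
5. **Validation** — one-to-one lesion matching (SUVmax difference +
   Euclidean distance cost), voxel-wise sensitivity/specificity in the bone
   domain, Dice similarity, Pearson concordance of volume and SUVmean, a
   threshold sweep with ROC points, optimum-threshold selection, per-patient
   report and a missed-lesion audit.
6. **Phantom** — co-registered synthetic CT/PET with bone cylinders,
   extra-osseous hot organs and spherical lesions of known volume and SUV
   plateau, exported as DICOM series + RTSTRUCT + ground-truth NIfTI.

## CLI

```sh
# generate a synthetic phantom (DICOM PET + CT series, RTSTRUCT, truth NIfTI)
osteoseg phantom --out work/ph --preset widespread --seed 1 --noise-suv 0.1

# run the segmentation pipeline
osteoseg segment --pet-dir work/ph/pet --ct-dir work/ph/ct \
    --out work/seg --suv-th 3.0 --hu-th 110

# validate against reference contours (RTSTRUCT)
osteoseg validate --pet-dir work/ph/pet --ct-dir work/ph/ct \
    --ref work/ph/rtstruct.dcm --out work/val

# sweep SUV thresholds and pick the optimum (max sensitivity+specificity)
osteoseg sweep --pet-dir work/ph/pet --ct-dir work/ph/ct \
    --ref work/ph/rtstruct.dcm --out work/sweep \
    --thresholds 2.0,2.5,3.0,3.5,4,6
```

`segment` writes the SUV map, bone mask and lesion label map as NIfTI, a
per-lesion CSV (`label,volume_ml,suv_mean,suv_max,x,y,z`) and a JSON summary
echoing the effective configuration. `validate` adds the per-patient report
CSV, a metrics JSON and the unmatched-lesion audit CSV; `sweep` writes the
per-threshold metric table and ROC point list. A YAML config file
(`--config`) can set any default; explicit flags win over the file.

## Conventions

- Volumes are indexed `[x, y, z]`; physical mm = origin + index · spacing;
  0-based voxel indices; axial, axis-aligned grids only.
- SUV is body-weight SUV: `SUV = C · 1000 · W / (D · 2^(−Δt/T½))` with C in
  Bq/ml, D the injected dose (Bq), W the weight (kg) and Δt the
  injection→scan-start interval (honouring the DecayCorrection header tag).
- Lesion thresholding is inclusive (SUV ≥ threshold); SUVmax ties resolve
  to the lexicographically smallest voxel index.
- Rasterisation uses the voxel-centre-in-polygon even-odd rule; overlapping
  RTSTRUCT structures resolve later-structure-wins.
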