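# oculoshape

Quantification of 3D posterior-eye shape from binary MRI masks, a 12-feature
fundus morphometry battery, and random-intercept regression linking fundus
features to ocular asphericity — together with a synthetic-data generator so
the full pipeline is testable without any restricted imaging data.

## What it does

- **`oculoshape.eye_shape`** — loads binary posterior-eye masks (NIfTI +
  JSON laterality sidecar), fits a 3D ellipsoid to the full foreground
  volume by eigendecomposition of the voxel covariance (semidiameter =
  √(5·eigenvalue), the solid-uniform-ellipsoid relation), and derives:
  volume (voxel count × voxel volume), horizontal/vertical asphericity
  (b²/a² − 1, c²/a² − 1; negative = prolate, positive = oblate), radial RMS
  fit error, Dice overlap, and ICC(A,1) repeatability.
- **`oculoshape.fundus`** — computes the 12-feature battery from geometric
  scene annotations (OD ellipse, fovea, vessel polylines with widths):
  OD–fovea distance and angle, OD area/orientation/ovality, CRAE/CRVE
  (iterative big-six pairing, Knudtson constants 0.88/0.95), length-weighted
  arc/chord tortuosity, box-counting fractal dimension, temporal-arcade
  concavity, and foveal pixel intensity. Dimensional metrics are corrected
  for ocular magnification (ametropia + keratometry variant, factor = 1 at
  the emmetropic reference).
- **`oculoshape.association`** — standardizes predictors and fits linear
  mixed-effects (per-participant random intercept) models for SER–shape and
  feature–shape associations, REML by default with Wald 95% CIs.
- **`oculoshape.synthetic`** — voxelized rotated ellipsoids, fundus scenes
  and per-eye cohorts with fully recorded ground truth; all randomness flows
  from explicit seeds.
- **`oculoshape.cli`** — end-to-end orchestration with provenance output.

## CLI

```bash
oculoshape simulate --n-participants 100 --seed 1 --out-dir run/
oculoshape fit --mask eye.nii --sidecar eye.json --out shape.csv
oculoshape extract --scene scene.json --out features.csv
oculoshape assoc shape-models  --cohort run/cohort.csv --out table2.csv
oculoshape assoc feature-models --cohort run/cohort.csv --out table3.csv
oculoshape all --n-participants 100 --seed 1 --out-dir run/
```

`oculoshape all` generates a cohort, realizes every eye as a voxelized
ellipsoid and a fundus scene, re-measures both, merges the results and fits
all models; outputs are byte-identical across reruns with the same seed.
`provenance.json` records every methodological toggle (semidiameter scaling,
ICC form, tortuosity definition, caliber and magnification constants).

## Conventions worth knowing

- Voxel membership in the generator is decided at voxel centers; anisotropic
  spacing is handled by converting indices to mm, never by resampling.
- Eigen-axes are assigned to anatomical axes by maximal |dot product|; under
  strong obliquity the optimal bijection is used (opt into a hard error with
  `fit_ellipsoid(..., strict_axes=True)`).
- Missing fundus features are NaN sentinels, not exceptions; models skip
  all-missing columns with a logged reason.
- Left-eye scenes are mirrored before OD–fovea angle computation so that
  negative always means the fovea sits below the disc horizontal.
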