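# lcseg

Fully automatic locus coeruleus (LC) MRI analysis: two-stage 3-D U-Net
ensemble segmentation (localization → patch segmentation with majority
voting), geometric reference-region placement from an LC-oriented
coordinate frame, and LC feature extraction (contrast ratios, subregional
contrast ratios, signal length and volume). Because the clinical datasets
behind this family of methods are not public, the package ships a
synthetic phantom generator that emulates FLASH-like brainstem
acquisitions with ground-truth masks, and every component is exercised
end-to-end on phantoms.

The neural networks are implemented directly on numpy (hand-written
forward/backward passes routed through BLAS); no deep-learning framework
is required. The tiny default configurations train in minutes on one CPU.

## Layout

| module            | contents                                                          |
| ----------------- | ----------------------------------------------------------------- |
| `lcseg.volio`     | `Volume` / `BinaryMask` / `HemiMaskPair`, NIfTI I/O, sinc (Fourier) upsampling |
| `lcseg.phantom`   | `PhantomSpec`, `generate_phantom`, `generate_dataset`             |
| `lcseg.nets`      | fold plans, numpy 3-D U-Net, ensemble training, localization, majority vote |
| `lcseg.pipeline`  | `run_inference`: localize → crop → z-score → segment → split hemispheres |
| `lcseg.refregion` | LC coordinate frame (v1, v2, v3), offset learning, reference-box placement |
| `lcseg.features`  | CRmax/CRmedian, subregional CRs (halves/thirds), length (mm), volume (mm³) |
| `lcseg.evaluate`  | DSC, sensitivity/specificity ("accuracy"), probabilistic templates, Cohen's d |

## CLI

```sh
# generate 20 phantoms (volume_###.nii.gz, lc/ref masks, manifest.json)
lcseg phantom --n 20 --out data/ --seed 1 [--config spec.yaml] [--jitter 0.08]

# train the 5-member two-stage ensemble on a phantom directory
lcseg train --data data/ --config net.yaml --out model.lcseg

# segment one volume (writes *_lc_left/right.nii.gz + *_qc.json)
lcseg segment --model model.lcseg --in data/volume_000.nii.gz --out-prefix sub01

# place reference regions from LC masks and a learned offset model (JSON)
lcseg refregion --offsets offsets.json --lc-left sub01_lc_left.nii.gz \
    --lc-right sub01_lc_right.nii.gz --volume data/volume_000.nii.gz \
    --out-prefix sub01

# features CSV: one row per scope (left / right / bilateral)
lcseg features --in data/volume_000.nii.gz \
    --lc-left ... --lc-right ... --ref-left ... --ref-right ... --out features.csv

# per-subject per-side DSC/sensitivity/specificity report
lcseg evaluate --pred-dir preds/ --ref-dir data/ --out report.csv

# print a 3x5 nested cross-validation plan
lcseg folds --n 82
```

YAML configs map directly onto `PhantomSpec` and `NetConfig` fields.

## Conventions

- Voxel indices are 0-based; world coordinates follow the NIfTI affine
  (RAS+). "Axial" means the grid axis closest to the world superior axis.
- Left/right hemispheres are resolved in world space from the affine,
  never from grid indices.
- Masks are hard {0,1} labels on the working grid; no sub-voxel mask
  interpolation anywhere.
- Frame order is (v1, v2, v3): v1 ≈ rostrocaudal, v2 ≈ anterior, v3
  toward the anatomical left; offsets are stored in mm.
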