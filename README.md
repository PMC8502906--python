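# pelvimotion

Intrafractional motion modelling of the male pelvis from 4D image series.

During a radiotherapy fraction the prostate drifts by a few millimetres,
pushed by bladder filling and rectal motion. On an MR-Linac a short dynamic
scan acquired before treatment can serve as an individualised learning set:
registering each time frame to the first yields displacement vector fields
(DVFs), and a principal-component decomposition of those fields gives a
compact, patient-specific model of the ongoing drift. `pelvimotion`
implements that workflow end to end:

* **phantom** — a synthetic 4D pelvic phantom (prostate, bladder, rectum as
  ellipsoids with smooth intensity ramps) with slow monotone bladder
  filling, anterior rectal drift and coupled prostate translation. The
  deformation is analytic, so every frame ships with its exact ground-truth
  displacement field.
* **registration** — multiscale Horn–Schunck optical flow (three pyramid
  levels, factor 2, optimisation stopped at half resolution for a smooth
  field), registering every frame to the reference frame.
* **metrics** — DICE overlap, average (symmetric mean) Hausdorff distance
  between segmentation edges, and the inverse-consistency vector magnitude
  error (VME) of a forward/backward registration pair.
* **motion_model** — PCA restricted to the segmentation-boundary voxels.
  With unit-norm components `PC_n` and eigenvalue-ordered spectrum, a new
  field is modelled as

  ```
  x_model = x̄ + Σ_{n≤k} w_n · PC_n,          ‖PC_n‖ = 1,
  w_opt,n = (x − x̄) · PC_n,
  ε_i     = ‖x_model − x_ref‖_i   (mm, per boundary voxel)
  ```

  using the first five DVFs for training and the remaining four for
  validation.
* **inversion** — fixed-point displacement-field inversion
  (`v ← −u(r + v)`), plus densification of the boundary-only model field
  into a narrow band so the reference segmentation can be deformed into a
  model-predicted segmentation and scored with DICE.
* **evaluation** — the full multi-subject study: per-frame registration
  quality, cumulative explained variance, residual/DICE versus training-set
  size and component count, and cumulative residual-frequency curves.

## Worked example

```python
from pelvimotion import (
    PhantomConfig, generate_series, register_series,
    extract_boundary, build_model, cumulative_variance, fit_field,
)

frames = generate_series(PhantomConfig(grid_shape=(64, 64, 32),
                                       spacing_mm=(1.5, 1.5, 3.0)))
fields = register_series([f.image for f in frames])

boundary = extract_boundary(frames[0].masks, "joint")
model = build_model(fields[1:6], boundary)        # first five DVFs train
print("cumulative variance:", cumulative_variance(model).round(3))
for t in range(6, 10):                            # last four validate
    fit = fit_field(model, fields[t])
    print(f"frame {t}: mean residual {fit.mean_residual:.3f} mm")
```

Output:

```
cumulative variance: [0.814 0.895 0.96  1.   ]
frame 6: mean residual 0.147 mm
frame 7: mean residual 0.140 mm
frame 8: mean residual 0.180 mm
frame 9: mean residual 0.224 mm
```

The first principal component explains 81% of the training-set motion, and
the fitted model leaves mean residuals of 0.14–0.22 mm on the validation
frames — against a no-model baseline of ≈0.8 mm (compare
`results/acceptance.json` after the reproduction run below).

The same pipeline is scriptable from the shell:

```bash
pelvimotion simulate --seed 1 --out series/
pelvimotion register-series --manifest series/manifest.yaml --out fields/
pelvimotion build-model --manifest series/manifest.yaml --fields fields/ \
    --train-frames 5 --out model.npz
pelvimotion fit-model --model model.npz --field fields/dvf07.nii.gz
pelvimotion run-experiment --subjects 9 --seed 0 --out report/
```

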