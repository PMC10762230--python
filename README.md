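# rotomo — autonomous cell-rotation optical projection tomography

Optical projection tomography (OPT) reconstructs a 3D object from 2D
projections taken at many orientations — the optical analogue of CT.
Conventional single-cell OPT scans the *illumination* over the cell, but the
numerical aperture of microscope objectives caps the scan at roughly 160°,
leaving an unsampled wedge of Fourier space (the "missing cone") that blurs
the reconstruction along one axis.  Rotating the *cell* itself — for example
in a fiber-optic optical trap inside a microfluidic chip — covers the full
half-turn and restores isotropic resolution, provided the rotation angle of
every video frame can be recovered.

`rotomo` implements that reconstruction workflow for researchers doing
single-cell tomography with any cell-rotation modality (optical trapping,
microflow, dielectrophoresis, acoustic streaming):

1. **Preprocess** — detect the cell (Otsu + connected components, trained
   detectors pluggable), crop to a stabilized window, segment, and
   center-align every frame on the minimal enclosing circle (Welzl's
   algorithm) of the cell contour.
2. **Track the rotation** — Harris corners seed a pyramidal Lucas–Kanade
   tracker with blob-centroid refinement.  A rigid feature at longitude φ on
   a cell rotating about the vertical image axis moves laterally as

       col(t) − axis = r · sin(φ + θ_t),

   so the per-frame angle follows from the arcsine of the normalized
   displacement.  Its derivative `r·cos(φ+θ)` vanishes when the feature
   crosses the silhouette — pixel quantization then stalls the tracked angle
   (a *stagnation* plateau) — so many features are tracked from both ends of
   the video and fused by a robust joint least-squares solve for the
   per-frame angle θ_i.
3. **Reconstruct** — every aligned image row is a sinogram `R(θ, p)`; by the
   Fourier slice theorem its 1D spectrum is a central slice of the object's
   spectrum, inverted by filtered back-projection (ramp-family filters,
   trapezoidal Δθ weights so non-uniform estimated angles need no
   resampling).  Slices stack into the 3D intensity volume `f(x, y, z)`.
4. **Evaluate** — MSE, MAE, RMSE, multiscale SSIM and PSNR against a known
   ground truth, plus the relative improvement over a 160° limited-angle
   baseline that emulates conventional illumination scanning.

A cell-phantom simulator (spherical cell with nucleus, organelles and
bright surface beads, rendered as parallel line integrals with known truth
angles) provides the validation substrate; phantom and video generation are
first-class, tested code.

## Worked example

```python
from rotomo import PipelineConfig, default_phantom_spec, run_pipeline

cfg = PipelineConfig(phantom=default_phantom_spec(), out_dir="run", seed=1)
result = run_pipeline(cfg)
print(result.tracking.mean_error)
print(result.comparison.relative_change)
```

Running `examples/03_reconstruct_volume.py` (the same computation) prints:

```
tracking mean error: 1.34 deg
reconstructed volume: (128, 128, 128) voxels at 0.15 um

metric      full-angle   160-deg-limited
mse             0.0134       0.0221
mae             0.1121       0.1435
rmse            0.1158       0.1488
ms_ssim         0.6635       0.6174
psnr           18.7289      16.5476

relative change of the full-angle reconstruction (positive = better):
  mse: +39.5%
  mae: +21.9%
  rmse: +22.2%
  ms_ssim: +7.5%
  psnr: +13.2%
```

The fused rotation angle tracks the ground truth to 1.34° mean absolute
error on this video, and the full-angle reconstruction beats the 160°
limited-angle baseline on all five metrics — the missing-cone blur is the
difference.  The other scripts in `examples/` demonstrate the phantom
simulator, tracking in isolation, and the stagnation/fusion phenomenon.

A thin CLI mirrors the stages (`rotomo simulate | preprocess | track |
reconstruct | evaluate | run | fixtures`); run `rotomo run --out run --seed 1`
for the end-to-end workflow on a simulated phantom, or pass `--in` with a
recorded rotation video (multi-page TIFF or a directory of frames).

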