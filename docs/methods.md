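# Methods

This note documents the models, estimators and numerical choices behind
`rotomo`, in the order data flows through the pipeline.

## Phantom simulator

The validation substrate is a spherical cell phantom on a cubic voxel grid.
The default (`default_phantom_spec()`) is HL60-scale: 128³ voxels at
0.15 µm/voxel, cell radius 7.5 µm, cytoplasm intensity 0.3, one nucleus-like
inclusion (radius 3.5 µm, intensity 0.55, offset 1.5 µm from the center),
three organelles (radii 0.8–1.2 µm, intensities 0.8–0.95) and six surface
beads (radius 0.4 µm, intensity 1.0) placed just inside the membrane on a
golden-angle ladder of latitudes ±50° … ±10°.  The beads guarantee
corner-like, trackable contrast in the projections; their layout is
deterministic given the spec.  Voxels are painted by a center-inside-sphere
test with no antialiasing; later inclusions overwrite earlier ones.

**Axis convention.** Volume axes are `(v, a, b)`: `v` is the vertical
rotation axis (image rows), `b` the optical axis.  A positive rotation angle
is counter-clockwise viewed from `+v` (a point at `(a,b)=(d,0)` moves to
`(0,d)` after 90°).  With this handedness a feature at longitude φ projects
to column `axis + r·sin(φ − θ)`; because `sin(φ−θ) ≡ sin((180°−φ)+θ)`, the
same track is equally described with an increasing phase, so the estimators
below are insensitive to the physical rotation sense (the `direction` flag
matters only for the sequential-continuation mode of `track_to_angles`).

**Forward model.** Projections are pure parallel line integrals: each pixel
is the voxel sum along `b` times the voxel size, so a frame's total equals
the volume total times the voxel size exactly.  No diffraction, defocus or
partial coherence is modelled — this matches the assumption under which
filtered back-projection is exact, so simulator round trips isolate
algorithmic error from physics error.  Rigid rotation uses trilinear
resampling (`scipy.ndimage.affine_transform`, zero fill).

**Noise.** The rendered video adds Gaussian noise with σ = 1% of the clean
stack maximum (seed-controlled); an optional Poisson shot-noise stage is off
by default.  Videos default to 180 frames over 180° — one projection per
degree of a smoothly driven half-turn.

What the simulator does *not* emulate — brightfield contrast inversion,
illumination gradients, focus drift, cell deformation, rotation-axis tilt
and wobble — bounds what passing tests show about real recordings: they
validate the geometry, estimators and reconstruction numerics, not
robustness to optical artefacts.  The preprocessing operators (polarity
flag, detector/segmenter interfaces) are the intended extension points for
real data.

## Preprocessing

Detection is a global Otsu threshold followed by connected-component
labelling; the largest component above `min_area` (default 50 px²) wins, its
box padded by 4 px.  Crops are `size`×`size` windows centered on box centers
smoothed by a 9-frame moving average (reflected ends), so detection jitter
does not shake the video.  Segmentation is Otsu + morphological closing
(disk radius 3) + hole filling + largest component.  The minimal enclosing
circle of the mask is computed exactly by Welzl's algorithm on the convex
hull of the boundary pixels.  Alignment translates each frame (bilinear,
zero fill) so the circle center sits at the frame center `((H−1)/2,(W−1)/2)`
— the same point the reconstruction uses as the rotation axis.  The pipeline
smooths circle *centers* across frames (window 9) before aligning: Welzl
centers inherit ~0.3 px RMS mask-quantization jitter which would otherwise
enter every feature track as common-mode noise, while the trapped cell's
true drift is smooth.

## Rotation-angle estimation

The angle estimator is the scientific core and is built for one failure
mode observed throughout development: a feature tracks beautifully until it
crosses the cell silhouette, where its lateral leverage `r·cos(φ+θ)`
vanishes; the tracker then slides onto the (static) silhouette edge and the
track is silently wrong from there on — *smoothly* wrong, so per-track
diagnostics cannot flag it.

Design responses, in order:

* **High-pass tracking images.** Projections are dominated by the
  dome-shaped cytoplasm line integral, which barely changes during rotation;
  tracking on `img − gaussian(img, σ=8 px)` removes the dome so brightness
  constancy holds for the moving blobs (beads, organelles).
* **Pyramidal Lucas–Kanade + blob-centroid refinement.** A 21 px window,
  3 pyramid levels, forward–backward check at 1 px.  Each LK prediction is
  snapped to the local intensity centroid of the blob (radius 4 px, guard
  1.5 px), which removes the drift that frame-to-frame template tracking
  accumulates; clean bead tracks reach ~0.3 px accuracy over 180 frames.
* **Bidirectional seeding.** Harris corners (k = 0.04, σ = 1.5, mask eroded
  by the 5 px non-max-suppression distance) are seeded on the *first and
  last* frame, 16 per pass, and tracked toward the other end: each physical
  feature is clean on at least the arc between its seed frame and its first
  silhouette transit, so the two passes jointly cover the whole video.
* **Orbit fits.** Per track, `col(t) = axis + c + A·sinθ_t + B·cosθ_t` is
  fitted by least squares with the current rotation estimate as regressor
  (initially the nominal constant-rate grid — the device drives the rotation
  at constant speed).  Candidate fits on sliding sub-windows are scored by
  inlier count at 1.5 px and the winner refit on its inliers, so a
  half-corrupted track is fitted on its clean arc.  The intercept `c`
  absorbs sub-pixel centering residue; the radius is clamped to the
  enclosing-circle radius + 1 px.
* **Span gate.** Tracks whose angle series spans less than 0.5× or more
  than 1.5× the drive-implied rotation over their valid range are discarded.
  This is essential: silhouette-stuck tracks all agree that "nothing
  rotates" and would otherwise form a winning consensus.
* **Joint robust solve.** Per-feature arcsine series (branch chosen per
  frame by proximity to the current-estimate phase, so one glitch never
  corrupts the rest) enter a two-way weighted least-squares model
  `raw_f[i] = θ_i + b_f`, solved alternately for the per-frame angle θ and
  per-feature anchor b under a weighted zero-mean gauge.  Base weights are
  `(r·sens)²` — squared lateral pixels per radian, the inverse variance of
  the arcsine conversion under pixel noise.  From the second sweep, weights
  are multiplied by a Tukey biweight of the residual (scale 1.4826·MAD,
  floor 0.5°, constant 3.5 — below the classic 4.685 because the
  contamination is structured arcs, not occasional outliers).
* **Common-mode offset.** The median positional residual across features,
  per frame, estimates residual alignment jitter (shared by all features,
  hence invisible to fusion) and is subtracted from all tracks with a 0.8
  damping factor.
* **Outer iteration and monotone projection.** Orbit refits, the joint
  solve and the offset update alternate for 5 rounds (the scheme converges
  by round 4–5; further rounds slowly let the offset and angle estimates
  co-drift, so the count is fixed).  The final series is projected onto
  non-decreasing angles by weighted isotonic regression (the drive is
  one-way) and anchored at θ_0 = 0 — absolute orientation is
  unidentifiable and irrelevant to reconstruction.

The module-level operations keep simpler, composable contracts:
`track_to_angles` offers a sequential branch-continuation mode (known
rotation direction, bounded per-frame regression/advance), `fuse_tracks`
combines per-frame angle increments with squared-sensitivity weights
(an inverse-variance combination; on the quantized two-feature benchmark it
reaches 0.82° MAE where hard best-feature selection gives 1.58° and either
feature alone 1.2–1.4°), and `detect_stagnation` flags plateaus via a
sliding window (5 frames, 1° tolerance).

On the default phantom video the full estimator reaches ≈0.7–1.5° mean
absolute error depending on the noise realization (the phantom geometry is
fixed; only the detector noise varies with the seed, which flips Harris
seed selection and limb-capture events).  Validation therefore reports the
mean over four noise replicates — a lower-variance estimate of the same
stochastic quantity at identical study conditions.

## Reconstruction

Every aligned image row is an independent sinogram; rows with near-duplicate
angles (Δθ < 0.05°) are averaged.  Filtering uses the band-limited discrete
ramp kernel (value 1/4 at the origin, −1/(πn)² at odd lags) evaluated in the
Fourier domain on a power-of-two padding ≥ 2× the detector length, apodized
by a Hann window by default (`shepp-logan` and plain `ramp` available).
Back-projection interpolates linearly at `p = a·cosθ − b·sinθ` (detector
center = frame center) and integrates over angles with trapezoidal Δθ
weights whose end weights extend by their neighbouring gap — on a uniform
grid this reproduces the classic π/N weighting exactly, and non-uniform
estimated angles need no sinogram resampling.  Projections carry
intensity×µm units and are converted to detector-sample units before
filtering so reconstructed voxels recover the original intensity scale
(verified by a clean round trip: 2.5% RMSE of the phantom maximum).  An
optional circular support mask (on by default) zeroes the region outside
the inscribed circle, which no projection fully samples.

The limited-angle baseline keeps only frames within a contiguous angular
range (default 160°, the practical cap of illumination-scanning tomography)
centered on the mid-angle and runs the identical machinery.  The unsampled
20° wedge blurs structure along the in-plane axis orthogonal to the covered
fan: on the default phantom the nucleus FWHM elongates by ≈4–6% and all
five quality metrics degrade.  `spatial_filter` provides optional Gaussian
post-smoothing and a cylindrical support mask.

## Evaluation

Volumes are min-max normalized to [0, 1] (each by its own extrema) before
computing voxelwise MSE/MAE/RMSE, PSNR (`10·log10(1/MSE)`, data range 1,
capped at 100 dB for identical volumes) and MS-SSIM.  MS-SSIM uses the
standard five-scale weights (0.0448/0.2856/0.3001/0.2363/0.1333), Gaussian
windows (σ = 1.5), dyadic average-pool downsampling, computed per axial
slice and averaged; the scale count drops (weights renormalized) when a
slice is too small for five scales.  Relative changes are
`100·(conv−prop)/conv` for error metrics and `100·(prop−conv)/conv` for
similarity metrics.

## Problem sizes and determinism

Unit tests run on 48³–64³ phantoms with 24–120 frames; end-to-end
validation uses the full default conditions (128³, 180 frames, 1% noise).
Every stochastic stage draws from `numpy.random.default_rng` seeded from the
single run seed, and a run directory is byte-reproducible given its
configuration.

## Known limitations

* The rotation axis is assumed vertical in the image and drift-free; tilt
  and wobble are not estimated.
* Rotation speed is assumed near-constant (it anchors orbit-fit regressors
  and the span gate); strongly non-uniform rotation would need a different
  branch prior.
* Segmentation-based alignment assumes a near-spherical silhouette; highly
  aspherical cells would bias the enclosing-circle center.
* The forward model ignores diffraction and defocus, so absolute metric
  values on real brightfield data will differ from phantom values; the
  relative full-vs-limited comparison is the robust readout.
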