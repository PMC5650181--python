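# vesseltrace

PSF-aware 3D vessel centerline tracing and in vivo / ex vivo vascular
network comparison for two-photon fluorescence microscopy (2PFM) of the
cerebral cortex.

## The problem

Optical clearing (e.g. fructose-based media) lets 2PFM image the cortical
vasculature millimetres deep, but imaging a high-refractive-index sample
through a water-immersion objective causes spherical aberration: the axial
width of the point spread function (PSF) grows roughly linearly with depth.
For capillaries — whose diameters are comparable to the PSF — an unmodelled
PSF inflates the apparent diameter, and the inflation grows with depth.
Comparing a cleared ex vivo specimen with the same tissue imaged in vivo
additionally requires non-rigid registration, re-measurement of diameters in
a common image space, and bookkeeping of in vivo-only artefacts (depth
attenuation of signal, shadows beneath pial vessels, unperfused vessels).

`vesseltrace` implements that whole chain as a tested library + CLI:

* **phantoms** — synthetic image stacks with exact ground truth: Gaussian-
  profile tubes convolved with a depth-varying anisotropic Gaussian PSF,
  exponential depth attenuation, geometric shadow columns, bead stacks for
  calibration, and matched in vivo / ex vivo volume pairs.
* **psf_model** — the PSF model (constant lateral FWHM; axial FWHM
  `a + b·depth`), its calibration from bead stacks by 1D Gaussian profile
  fits + OLS regression against depth, the refractive axial scale factor
  `n_agent/n_water`, and the marginal PSF covariance in the plane
  perpendicular to a vessel.
* **preprocess** — the conditioning chain (2D Gaussian blur of FWHM 1.5 μm
  per plane → isotropic 1.5 μm resampling → non-local-means denoising) and
  the metadata-only axial step correction for cleared tissue.
* **tracking** — medial-atom centerline tracing. A vessel cross-section is
  an isotropic 2D Gaussian (FWHM = diameter); convolved with the PSF
  marginal it defines an *ellipse* — the half-maximum contour — probed by 8
  spokes. The fitted radius maximizes the scale-normalized sum of inward
  intensity gradients at the spoke tips; low-gradient spokes flag branches;
  short free-end "hairs" are pruned. `recompute_diameters` re-measures radii
  under any assumed PSF with positions frozen.
* **network** — the vessel graph (vertices, edges, segments between
  junctions/free ends), interpolating 3D thin-plate-spline registration
  from landmark pairs, mutual-nearest-neighbour vertex matching, and
  tab-separated network / CSV landmark I/O.
* **morphometry** — capillary (< 8 μm, non-penetrating) and
  penetrating-vessel classification (greedy smallest-angle-to-normal
  descent), perfusion scoring by contrast-to-noise ratio, shadow labelling
  beneath pial vessels, large-vessel signal normalization, attenuation-length
  fits (`signal ∝ exp(−2·depth/ℓ)`), and matched diameter-ratio statistics.

## Worked example

Calibrate the PSF from a synthetic bead stack, then trace a 4 μm vessel at
800 μm depth and see what ignoring the depth variation would have done:

```python
import numpy as np
import vesseltrace as vt

# true optics: axial FWHM 3.4 um at the surface, +0.0041 um per um of depth
psf_true = vt.PSFModel(lateral_fwhm=1.0, axial_fwhm_intercept=3.4,
                       axial_fwhm_slope=0.0041)

# 1. bead stack -> per-bead Gaussian fits -> linear depth model
vol, table = vt.render_bead_phantom(vt.BeadPhantomSpec(n_beads=40,
                                                       psf=psf_true,
                                                       rng_seed=5))
vol = vt.blur_xy(vol, 1.5)                      # same blur as the images
fits = []
for _, row in table.iterrows():
    guess = row[["x_um", "y_um", "z_um"]].to_numpy(float)
    fx = vt.fit_bead_fwhm(vol, guess, "x")
    fx.fwhm_z = vt.fit_bead_fwhm(vol, guess, "z").fwhm_z
    fits.append(fx)
model, summary = vt.calibrate_psf_depth_model(fits)
print(f"axial FWHM(depth) = {model.axial_fwhm_intercept:.2f} "
      f"+ {model.axial_fwhm_slope:.4f} * depth  [um]")
print(f"lateral FWHM = {model.lateral_fwhm:.2f} um "
      f"(slope vs depth p = {summary['lateral_slope_pvalue']:.2f})")

# 2. a 4 um tube at 800 um depth on the native 0.994 x 0.994 x 1.5 um grid
from vesseltrace.phantoms import PhantomSpec, TubeSpec
cl = np.array([[5.0, 25.0, 800.0], [75.0, 25.0, 800.0]])
spec = PhantomSpec(volume_shape=(34, 51, 81), voxel_size=(0.994, 0.994, 1.5),
                   tubes=[TubeSpec(cl, 4.0, 1000.0)], origin=(0, 0, 775.0),
                   noise_model="gaussian", rng_seed=2)
img, truth = vt.render_vessel_phantom(spec, psf_true)
img = vt.standard_chain(img)                    # blur -> resample -> denoise
net = vt.track_image(img, model,
                     vt.TrackerConfig(psf=model, seed_threshold=200.0))
print(f"traced {net.n_vertices} vertices; "
      f"median diameter {np.median(2 * net.radii):.2f} um (true 4.0)")

# 3. re-measure pretending the PSF does not grow with depth
flat = vt.PSFModel(model.lateral_fwhm, model.axial_fwhm_intercept, 0.0)
net_flat = vt.recompute_diameters(net, img, flat)
pct = 100 * np.abs(net_flat.radii - net.radii) / net.radii
print(f"constant-PSF re-measurement inflates the diameter by "
      f"{np.median(pct):.1f}%")
```

Output:

```
axial FWHM(depth) = 3.46 + 0.0040 * depth  [um]
lateral FWHM = 1.86 um (slope vs depth p = 0.12)
traced 48 vertices; median diameter 3.88 um (true 4.0)
constant-PSF re-measurement inflates the diameter by 18.3%
```

The calibration recovers the generating optics (the fitted widths absorb
the 1.5 μm conditioning blur, which is why the lateral value exceeds 1 μm);
tracking with the calibrated model recovers the true diameter within a few
percent even at 800 μm depth; and assuming a depth-invariant PSF would have
reported this capillary ~18% too wide.

The same operations are available from the shell:

```bash
vesseltrace phantom beads --out-dir beads/ --seed 5
vesseltrace calibrate-psf --beads beads/beads.tiff --centers beads/centers.csv --out psf.yaml
vesseltrace preprocess --in raw.tiff --out cond.tiff --rescale-axial
vesseltrace track --in cond.tiff --psf psf.yaml --out net.tsv
vesseltrace register --landmarks lm.csv --network exvivo.tsv --direction ex2in --out warped.tsv
vesseltrace morphometry --network net.tsv --out report/
```

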