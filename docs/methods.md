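# Methods

## Imaging model

A two-photon stack is modelled as bright tubular structures on a dark
background, blurred by an anisotropic 3D Gaussian PSF. All Gaussian widths
use the single conversion FWHM = 2·sqrt(2·ln 2)·σ.

**PSF.** Constant lateral FWHM; axial FWHM linear in depth below the
cortical surface, `FWHM_z(depth) = a + b·depth`. The in vivo case is the
special case `b = 0` (defaults a = 3.4 μm). For cleared tissue imaged
through a water-immersion objective the defaults are a = 3.4 μm and
b = (7.5 − 3.4)/1000 μm/μm, i.e. 7.5 μm at 1 mm. The PSF is axis-aligned; no
astigmatism terms are modelled.

**Refractive axial scaling.** Focusing into a medium of index `n_agent`
with a water-dipped objective stretches the true focal displacement: the
apparent axial step is multiplied by `n_agent / n_water` (1.49/1.33 ≈ 1.12
for fructose-based clearing media). The correction is metadata-only (the z
spacing changes, voxel data do not); the subsequent isotropic resampling
realizes it on the grid, avoiding a double interpolation.

**Vessel cross-section.** An isotropic 2D Gaussian in the plane
perpendicular to the local tangent, with FWHM equal to the vessel diameter.
Reported diameters are therefore PSF-deconvolved Gaussian-FWHM diameters.

## Synthetic scenes

The phantom generator renders exactly this model, so every downstream stage
can be tested against known truth:

* A tube is the line integral of isotropic 3D Gaussians along its
  centerline. Because the PSF is Gaussian too, the convolution is folded
  into the kernel covariance — `σ_v² I + diag(σ_lat², σ_lat², σ_ax(depth)²)`
  evaluated at each centerline sample's own depth — which makes the
  rendering analytic and continuous in depth (no slab quantization). The
  per-length amplitude is chosen so the *pre-PSF* tube peak equals the
  requested intensity; total intensity is then conserved under any PSF
  width, and the observed peak falls as the PSF widens, as in real data.
  An optional hard-disk profile (rasterized indicator, slab-wise blur with
  the PSF held constant over ≤ 10 μm slabs) exists for model-mismatch
  experiments.
* Depth attenuation multiplies the tube field by `exp(−2·depth/ℓ)` (the
  two-photon convention: detected fluorescence decays at twice the
  excitation attenuation rate). Shadow regions are xy-polygons whose
  transmission factor multiplies the whole column — a purely geometric
  stand-in for absorption by pial vessels; no scattering physics.
* Beads are rendered as Gaussians of FWHM `sqrt(bead² + PSF²)` per axis
  (the 0.5 μm bead is far below the PSF width, so the Gaussian-equivalent
  approximation errs < 1%); bead centres are rejection-sampled with a
  12 μm minimum separation.
* Noise: none, additive Gaussian (default σ = 5% of the tube peak), or
  scaled Poisson. Identical spec + seed ⇒ bit-identical volumes.
* The default benchmark scene is 20 gently curved non-overlapping tubes
  (diameters log-uniform 3–12 μm, centerline separation at least the sum of
  radii + 4 μm) with 3 Y-bifurcations in a 200³ μm field at 1.5 μm voxels,
  with the default 5% Gaussian noise.

What the phantoms do **not** emulate: non-Gaussian vessel profiles (except
the disk option), red-blood-cell motion, hematocrit and wavelength-dependent
scattering, stitching seams, motion artefacts, autofluorescence texture.
Passing on phantoms demonstrates correctness of the estimators under the
model's assumptions, not robustness to every property of real data.

## PSF calibration from bead stacks

Bead images are pre-blurred with the same 1.5 μm 2D Gaussian used on the
vascular images, so the calibrated widths absorb the conditioning blur.
Each bead centre is refined by centre-of-mass in a 7³-voxel window
(skipping this biases FWHM low), then a 4-parameter 1D Gaussian
(amplitude, centre, σ, baseline) is least-squares fitted to the intensity
profile along the lateral and the optical axis; fits with relative RMS
residual above 0.15 are excluded. Ordinary least squares of axial FWHM
against depth gives the intercept/slope (with 95% CI); OLS of the lateral
FWHM gives a slope p-value, and when the slope is not significant
(α = 0.05) the lateral width is the plain mean (beads weighted equally; no
quality weighting). Calibration requires ≥ 5 beads over ≥ 3 depths.

## Medial-atom tracking

**Boundary model.** At a candidate centre with tangent t, radius r and
depth z, the model cross-section covariance in the plane ⟂ t is
`C(r) = σ_v(r)² I + E Σ(z) Eᵀ`, where Σ(z) is the full PSF covariance and
E's rows are an orthonormal basis of the plane (marginalizing a Gaussian
projects its covariance). The boundary is the half-maximum contour
`x ᵀ C⁻¹ x = 2 ln 2`; eight spokes at equally spaced plane angles end where
their rays cross it.

**Metric.** Each spoke scores the inward radial intensity derivative at its
tip (central difference, step = half a voxel), multiplied by
`s^(2·ln2 − 1)` where s is the spoke length. This scale normalization is
chosen so that, for a Gaussian profile, the per-spoke score peaks exactly
when the model's half-maximum contour coincides with the observed one —
maximizing the summed score over r therefore recovers the deconvolved
diameter without bias, in every spoke direction simultaneously when the
PSF model is correct. Negative scores (intensity rising outward, i.e. the
contour cutting through a neighbouring structure) are *not* clipped; they
penalize oversized contours that straddle two vessels. The model covariance
used by the metric additionally includes the known measurement blur of
gridded data (interpolation + finite-difference box, ≈ voxel²/6 + h²/3),
which removes a few-percent diameter bias.

**Interpolation.** Intensities are sampled by cardinal cubic-spline
interpolation (cached coefficients per volume). The PSF-blurred images are
nearly band-limited at 1.5 μm voxels, so cubic interpolation is close to
exact, whereas trilinear sampling acts as a tent kernel and inflated
fitted diameters by up to ~10% in testing.

**Fitting.** Coordinate search: iterative intensity-centroid recentring in
the perpendicular plane (ellipse-matched window, local background
subtracted; the fixed point of the centroid map is the centre of a
symmetric cross-section), alternated with a radius search — a log-spaced
grid over the radius bounds followed by bounded golden-section refinement
(the raw metric can be multimodal off-centre). During marching the radius
bracket is ±35% of the previous atom (vessel calibre varies slowly), and
recentring is capped at 1 μm per step so junction blobs do not deflect the
chain. On noiseless tubes of 3–10 μm diameter at 0–900 μm depth the median
absolute diameter error is ≈ 1–3%.

**Validity tests.** An atom is rejected when its centre does not outshine
its own boundary, when any point inside its half-max ellipse is > 1.2×
brighter than the centre (off-centre/straddling fit), or — during marching —
when its centre signal drops below 30% of the chain's running median (the
chain slipped off the vessel). Termination: the mean positive spoke
gradient falls below a configurable fraction (default 0.1) of the image's
robust gradient scale (95th percentile of |∇I| over above-threshold
voxels), which makes tracking invariant to global intensity rescaling.

**Seeding and tracing.** Seeds are voxels above a threshold (user-set, or
Otsu by default) that are 6-neighbour intensity maxima (ties broken toward
the lowest linear index). Seeds are processed brightest-first; each chain
marches bidirectionally in 1.5 μm steps with the tangent updated by
exponential smoothing (weight 0.5) of successive centre differences, and
marks its interior (radius + 1 μm) in an occupancy mask, so seeds inside
already-traced vessels are skipped at negligible cost. Initial tangents
come from the local structure tensor. Spokes scoring below 0.6× the atom's
median spoke, and atoms whose radius jumps above 1.4× the chain median,
emit branch candidates that are traced immediately after the parent chain.
Chains are linked into a network by connecting endpoints to the nearest
vertex of another chain within radius-aware tolerance.

**Hair pruning.** A free-end segment is removed when its arc length does
not exceed the radius at its junction vertex by more than 8 μm (the
empirical allowance); pruning iterates to a fixed point and degree-2
junctions then dissolve. Paths between two junctions are never removed.

**Diameter re-measurement.** `recompute_diameters` freezes positions and
tangents and re-optimizes only the radius under an assumed PSF — used to
quantify the constant-PSF error and to re-measure a warped ex vivo tree in
the in vivo image.

## Registration and comparison

Landmark pairs (bifurcation points identified in both images) drive an
interpolating 3D thin-plate spline with kernel U(r) = r and affine part,
solved by the standard bordered system; side conditions make the transform
exactly affine when the landmarks are (residual at landmarks < 1e-6 μm;
≥ 5 non-coplanar pairs required). The "inverse" is a reverse-direction fit
on swapped pairs — a TPS has no closed form inverse — exact at landmarks
and < 1 μm round trip inside the landmark hull for smooth warps. Warping a
network moves vertices and re-derives tangents; radii are deliberately not
rescaled (they must be re-measured in the target image). Vertex
correspondence uses mutual nearest neighbours within 3 μm (2 voxels) to
avoid many-to-one collapse.

## Morphometry

* Segments: maximal paths whose interior vertices have degree 2; segment
  radius = mean of vertex radii, segment signal = mean of vertex signals.
* Penetrating vessels: from a user-placed near-surface marker, walk
  downward, at each junction following the outgoing segment with the
  smallest angle to the cortical surface normal; stop at a free end.
  Artery/venule identity stays a user-supplied label.
* Capillary: a non-penetrating segment with mean diameter < 8 μm.
* Perfusion: background voxels are those below a user threshold; per-vertex
  CNR = (signal − mean background)/std(background); a segment is unperfused
  when more than 50% of its vertices have CNR < 1.0 ("approached zero" is
  operationalized as CNR < 1, configurable). The flags are invariant to
  affine intensity rescaling with a consistently transformed threshold.
  "Vessel" is interpreted as *segment* (not whole tree).
* Shadowing: pial segments (mean depth < 50 μm, diameter > 10 μm — a proxy
  for the visual identification of pial vessels), dilated by their radii
  and projected to xy; a vertex is shadowed iff its (x, y) falls inside
  the union; segments take the majority vote.
* Signal normalization: segment signals divided by the mean over segments
  wider than 10 μm (that reference mean is exactly 1 afterwards).
* Attenuation: OLS of ln(signal) against depth over a user-chosen window;
  ℓ = −2/slope under the two-photon convention (a `factor` flag switches to
  the single-pass convention); stderr propagated from the slope. The fit
  window is a required parameter because it depends on where the signal is
  above the noise floor.
* Diameter comparison: per in vivo segment with ≥ 3 matched vertices,
  ratio = mean matched ex vivo radius / mean matched in vivo radius;
  summaries per class plus the fraction of capillaries larger in vivo.

## Problem sizes and numerical defaults

The test suite and the acceptance script run on desk-scale scenes chosen to
exercise every code path with exact ground truth: single-tube volumes of
~60×40×40 μm per (diameter, depth) cell; a 200³ μm 20-tube benchmark
(recall/precision ≥ 0.98 at 2 μm in testing); 40-bead calibration stacks
over 0–1000 μm; a 12-capillary attenuation scene over 0–300 μm depth with
ℓ = 171 μm (recovered within 2%); paired volumes with class-wise shrinkage
0.87 (capillaries) and 0.66 (penetrating vessels), both recovered within
0.03 through the TPS → matching → comparison pipeline.

Other defaults: radius bounds 1–15 μm; step length one voxel (1.5 μm);
reflect padding for all convolutions; non-local means with 3³ patches, 7³
search, filter strength tied to an estimated noise σ (a noiseless volume
changes < 1% RMS).

## Known limitations

* The tracker assumes Gaussian cross-sections; strongly non-Gaussian
  lumina (e.g. plasma-only rims) will bias diameters.
* Branch detection is heuristic (spoke dips + radius jumps); dense
  anastomoses may still be linked through endpoint proximity rather than
  detected junctions. Chains can terminate early at complex junctions; the
  multi-seed strategy re-covers the remainder from other seeds.
* The greedy smallest-angle rule for penetrating vessels is exactly the
  stated procedure, not a global optimum over paths.
* TPS accuracy degrades outside the landmark hull; matching by mutual
  nearest neighbour assumes the residual misalignment is below half the
  inter-vessel spacing.
* Attenuation fits assume a single exponential; layered cortex with
  depth-dependent scattering will show curvature that the model ignores.
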