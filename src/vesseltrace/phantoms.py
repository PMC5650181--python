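"""Synthetic image volumes with known ground truth.

The generators emulate the statistical structure of two-photon angiograms
that the tracker and PSF calibrator assume: bright tube-like vessels with
Gaussian cross-sections on a dark background, blurred by an anisotropic
Gaussian PSF whose axial width grows linearly with depth (cleared-tissue
imaging), exponential signal attenuation with depth (in vivo imaging),
multiplicative shadow columns beneath pial vessels, and sub-resolution
fluorescent beads for PSF calibration.

Rendering of Gaussian-profile tubes is analytic: a tube is the line integral
of isotropic 3D Gaussians along its centerline, and convolution with the
Gaussian PSF is folded into the kernel covariance evaluated at each centerline
sample's own depth (so the depth variation of the PSF is continuous, not
slab-quantized). An optional hard-disk profile is rendered by rasterizing the
tube indicator and blurring slab-by-slab, for model-mismatch experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import VesselNetwork, build_segments
from .psf_model import PSFModel, fwhm_to_sigma
from .volume import ImageVolume

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "BeadPhantomSpec",
    "render_vessel_phantom",
    "render_bead_phantom",
    "make_paired_phantom",
    "straight_tube_spec",
    "random_vessel_spec",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class TubeSpec:
    """One vessel: a continuous centerline (μm) with diameter and brightness.

    ``diameter`` may be a scalar or one value per centerline point; it is the
    FWHM of the tube's Gaussian cross-section (the convention under which the
    tracker reports diameters). ``profile`` may be ``"gaussian"`` (default,
    matches the tracker's model) or ``"disk"`` (hard-edged cylinder, for
    model-mismatch tests).
    """

    centerline: np.ndarray  # (k, 3) world μm, k >= 2
    diameter: float | np.ndarray
    peak_intensity: float = 1000.0
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        d = np.asarray(self.diameter, dtype=float)
        if np.any(d <= 0):
            raise ValueError("diameter must be > 0")
        self.diameter = (np.full(len(self.centerline), float(d))
                         if d.ndim == 0 else d.reshape(len(self.centerline)))
        if self.profile not in ("gaussian", "disk"):
            raise ValueError("profile must be 'gaussian' or 'disk'")


@dataclass
class PhantomSpec:
    """Scene description for a synthetic angiogram.

    noise_model: ``"none"``, ``"gaussian"`` (additive, sigma = ``noise_sigma``
    or, when None, 5% of the brightest tube peak) or ``"poisson"``
    (``voxels ~ Poisson(img / poisson_scale) * poisson_scale``).
    shadow_regions: list of ``(polygon_xy, transmission)`` with the polygon an
    (k, 2) array of world-μm xy vertices and transmission in [0, 1]; the
    factor multiplies every voxel in the xy-column (geometric shadowing).
    """

    volume_shape: tuple[int, int, int]  # (nz, ny, nx) voxels
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)  # μm (x, y, z)
    tubes: list[TubeSpec] = field(default_factory=list)
    background_level: float = 20.0
    noise_model: str = "gaussian"
    noise_sigma: float | None = None
    poisson_scale: float = 1.0
    attenuation_length: float | None = None
    shadow_regions: list = field(default_factory=list)
    surface_z: float = 0.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        for _, t in self.shadow_regions:
            if not (0.0 <= t <= 1.0):
                raise ValueError("shadow transmission must be in [0, 1]")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _resample_polyline(points: np.ndarray, values: np.ndarray, spacing: float):
    """Resample a polyline (and per-point values) at fixed arc-length spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[:1], values[:1], np.zeros((1, 3))
    si = np.arange(0.0, total + spacing / 2, spacing)
    pts = np.stack([np.interp(si, s, points[:, k]) for k in range(3)], axis=1)
    vals = np.interp(si, s, values)
    tans = np.gradient(pts, si, axis=0) if len(si) > 1 else np.zeros((1, 3))
    nrm = np.linalg.norm(tans, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return pts, vals, tans / nrm


def _deposit_gaussian_tube(img, vol: ImageVolume, pts, diams, peak,
                           psf: PSFModel, spacing):
    """Accumulate a PSF-convolved Gaussian tube by line-integral deposition."""
    size = np.array(vol.voxel_size)  # (sx, sy, sz)
    origin = np.array(vol.origin)
    nz, ny, nx = img.shape
    sig_lat = fwhm_to_sigma(psf.lateral_fwhm)
    inside = vol.contains(pts)
    if not np.all(inside):
        warnings.warn("tube extends outside the volume; clipping", stacklevel=3)
    sv = fwhm_to_sigma(diams)
    depth = np.maximum(pts[:, 2] - vol.surface_z, 0.0)
    sig_ax = fwhm_to_sigma(psf.axial_fwhm_at_depth(depth))
    sx = np.sqrt(sv**2 + sig_lat**2)
    sz = np.sqrt(sv**2 + sig_ax**2)
    amp = peak * spacing * sv**2 / (_SQRT2PI * sx * sx * sz)
    for i in np.nonzero(inside)[0]:
        c = pts[i]
        half = 4.0 * np.array([sx[i], sx[i], sz[i]])
        lo = np.floor((c - half - origin) / size).astype(int)
        hi = np.ceil((c + half - origin) / size).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, [nx, ny, nz])
        if np.any(hi <= lo):
            continue
        ax = origin[0] + np.arange(lo[0], hi[0]) * size[0] - c[0]
        ay = origin[1] + np.arange(lo[1], hi[1]) * size[1] - c[1]
        az = origin[2] + np.arange(lo[2], hi[2]) * size[2] - c[2]
        gx = np.exp(-0.5 * (ax / sx[i]) ** 2)
        gy = np.exp(-0.5 * (ay / sx[i]) ** 2)
        gz = np.exp(-0.5 * (az / sz[i]) ** 2)
        img[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += (
            amp[i] * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )


def _deposit_disk_tube(prepsf, vol: ImageVolume, pts, diams, peak):
    """Rasterize a hard-edged cylinder (pre-PSF) by nearest-sample distance."""
    size = np.array(vol.voxel_size)
    origin = np.array(vol.origin)
    nz, ny, nx = prepsf.shape
    for i in range(len(pts)):
        c, r = pts[i], diams[i] / 2.0
        lo = np.maximum(np.floor((c - r - size - origin) / size).astype(int), 0)
        hi = np.minimum(np.ceil((c + r + size - origin) / size).astype(int) + 1,
                        [nx, ny, nz])
        if np.any(hi <= lo):
            continue
        ax = origin[0] + np.arange(lo[0], hi[0]) * size[0] - c[0]
        ay = origin[1] + np.arange(lo[1], hi[1]) * size[1] - c[1]
        az = origin[2] + np.arange(lo[2], hi[2]) * size[2] - c[2]
        d2 = (az[:, None, None] ** 2 + ay[None, :, None] ** 2
              + ax[None, None, :] ** 2)
        blk = prepsf[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]
        np.maximum(blk, np.where(d2 <= r * r, peak, 0.0), out=blk)


def _convolve_depth_varying(prepsf, vol: ImageVolume, psf: PSFModel,
                            slab_um: float = 10.0):
    """Blur a pre-PSF volume with the depth-varying PSF, slab by slab.

    The PSF is held constant within slabs of ≤ ``slab_um`` (it varies slowly
    with depth); each output slab is the central part of a 3D Gaussian filter
    applied to a padded window around the slab.
    """
    from scipy.ndimage import gaussian_filter

    nz = prepsf.shape[0]
    sx, sy, sz_um = vol.voxel_size
    out = np.zeros_like(prepsf)
    slab_vox = max(1, int(round(slab_um / sz_um)))
    sig_lat = fwhm_to_sigma(psf.lateral_fwhm)
    for z0 in range(0, nz, slab_vox):
        z1 = min(z0 + slab_vox, nz)
        zc_world = vol.origin[2] + 0.5 * (z0 + z1 - 1) * sz_um
        depth = max(zc_world - vol.surface_z, 0.0)
        sig_ax = fwhm_to_sigma(psf.axial_fwhm_at_depth(depth))
        pad = int(np.ceil(4 * sig_ax / sz_um))
        w0, w1 = max(0, z0 - pad), min(nz, z1 + pad)
        blurred = gaussian_filter(
            prepsf[w0:w1], sigma=(sig_ax / sz_um, sig_lat / sy, sig_lat / sx),
            mode="reflect")
        out[z0:z1] = blurred[z0 - w0:z1 - w0]
    return out


def _shadow_map(spec: PhantomSpec, shape_yx):
    import shapely

    ny, nx = shape_yx
    tmap = np.ones((ny, nx))
    if not spec.shadow_regions:
        return tmap
    xs = spec.origin[0] + np.arange(nx) * spec.voxel_size[0]
    ys = spec.origin[1] + np.arange(ny) * spec.voxel_size[1]
    gx, gy = np.meshgrid(xs, ys)
    for poly_xy, trans in spec.shadow_regions:
        poly = shapely.Polygon(np.asarray(poly_xy, dtype=float))
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)
        tmap[inside] *= trans
    return tmap


def _apply_noise(img, spec: PhantomSpec, rng):
    if spec.noise_model == "none":
        return img
    if spec.noise_model == "gaussian":
        sigma = spec.noise_sigma
        if sigma is None:
            peak = max((t.peak_intensity for t in spec.tubes), default=0.0)
            sigma = 0.05 * peak
        img = img + rng.normal(0.0, sigma, size=img.shape)
        return np.clip(img, 0.0, None)
    # poisson
    lam = np.clip(img / spec.poisson_scale, 0.0, None)
    return rng.poisson(lam).astype(float) * spec.poisson_scale


def _ground_truth_network(spec: PhantomSpec, vol: ImageVolume,
                          vertex_spacing: float) -> VesselNetwork:
    pos, rad, tan, edges = [], [], [], []
    for tube in spec.tubes:
        pts, diams, tans = _resample_polyline(
            tube.centerline, tube.diameter, vertex_spacing)
        keep = vol.contains(pts)
        idx_map = {}
        for j in np.nonzero(keep)[0]:
            idx_map[j] = len(pos)
            pos.append(pts[j])
            rad.append(diams[j] / 2.0)
            tan.append(tans[j])
        for j in range(len(pts) - 1):
            if keep[j] and keep[j + 1]:
                edges.append((idx_map[j], idx_map[j + 1]))
    pos = np.array(pos) if pos else np.zeros((0, 3))
    net = VesselNetwork(
        positions=pos,
        radii=np.array(rad) if rad else np.zeros(0),
        edges=np.array(edges) if edges else np.zeros((0, 2), int),
        tangents=np.array(tan) if tan else np.zeros((0, 3)),
        depths=pos[:, 2] - vol.surface_z if len(pos) else np.zeros(0),
    )
    if net.n_vertices:
        net.signals = vol.interp(net.positions)
    build_segments(net)
    return net


def render_vessel_phantom(spec: PhantomSpec, psf: PSFModel,
                          vertex_spacing: float | None = None,
                          sample_spacing: float = 0.5):
    """Render a vessel scene through the imaging model.

    Each tube is a Gaussian cross-section profile (FWHM = local diameter)
    swept along its centerline and convolved with the PSF evaluated at each
    point's own depth. The tube field is then attenuated as
    ``exp(-2 * depth / attenuation_length)`` (two-photon convention), the
    background is added, shadow-column transmissions are applied
    multiplicatively, and the noise model is sampled.

    Returns
    -------
    (ImageVolume, VesselNetwork)
        The rendered volume and the ground-truth network with vertices
        sampled along each centerline (default spacing: one voxel), carrying
        the true radii and the rendered signal at the vertex.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = (int(s) for s in spec.volume_shape)
    vol = ImageVolume(np.zeros((nz, ny, nx)), spec.voxel_size,
                      spec.origin, spec.surface_z,
                      provenance=[{"op": "render_vessel_phantom",
                                   "seed": spec.rng_seed}])
    img = vol.voxels
    disks = []
    for tube in spec.tubes:
        pts, diams, _ = _resample_polyline(
            tube.centerline, tube.diameter, sample_spacing)
        if tube.profile == "gaussian":
            _deposit_gaussian_tube(img, vol, pts, diams, tube.peak_intensity,
                                   psf, sample_spacing)
        else:
            disks.append((pts, diams, tube.peak_intensity))
    if disks:
        prepsf = np.zeros_like(img)
        for pts, diams, peak in disks:
            _deposit_disk_tube(prepsf, vol, pts, diams, peak)
        img += _convolve_depth_varying(prepsf, vol, psf)

    if spec.attenuation_length is not None:
        zw = vol.origin[2] + np.arange(nz) * vol.voxel_size[2]
        depth = np.maximum(zw - spec.surface_z, 0.0)
        img *= np.exp(-2.0 * depth / spec.attenuation_length)[:, None, None]
    img += spec.background_level
    img *= _shadow_map(spec, (ny, nx))[None, :, :]
    vol.voxels = _apply_noise(img, spec, rng)

    if vertex_spacing is None:
        vertex_spacing = min(spec.voxel_size)
    truth = _ground_truth_network(spec, vol, vertex_spacing)
    return vol, truth


# ---------------------------------------------------------------------------
# Bead phantoms for PSF calibration
# ---------------------------------------------------------------------------


@dataclass
class BeadPhantomSpec:
    """Sub-resolution fluorescent beads in cleared agar, for PSF calibration."""

    n_beads: int
    psf: PSFModel
    bead_diameter: float = 0.5  # μm
    depth_range: tuple[float, float] = (0.0, 1000.0)  # μm
    voxel_size: tuple[float, float, float] = (0.994, 0.994, 1.5)
    xy_extent: float = 80.0  # μm field width
    peak_intensity: float = 1000.0
    background_level: float = 10.0
    min_separation: float = 12.0  # μm; beads may not overlap
    noise_model: str = "none"
    noise_sigma: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be > 0")
        if self.depth_range[1] < self.depth_range[0] or self.depth_range[0] < 0:
            raise ValueError("invalid depth_range")


def render_bead_phantom(spec: BeadPhantomSpec):
    """Render a bead stack; returns (ImageVolume, table of true centres).

    Each bead is rendered as its PSF-convolved image: since the bead diameter
    (0.5 μm) is far below the PSF width, the bead is modelled as a Gaussian
    of FWHM equal to its diameter, so the rendered spot is Gaussian with
    FWHM = sqrt(bead² + psf²) per axis, the PSF evaluated at the bead's
    own depth. The returned table lists exact centres and depths.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sx, sy, sz = spec.voxel_size
    margin = 10.0
    nz = int(np.ceil((spec.depth_range[1] + margin) / sz)) + 1
    nxy = int(np.ceil(spec.xy_extent / sx)) + 1
    vol = ImageVolume(np.zeros((nz, nxy, nxy)), spec.voxel_size,
                      provenance=[{"op": "render_bead_phantom",
                                   "seed": spec.rng_seed}])
    lo, hi = vol.world_extent()
    if spec.depth_range[1] > hi[2] or spec.depth_range[0] < lo[2]:
        raise ValueError("depth_range outside volume")

    centers = []
    attempts = 0
    while len(centers) < spec.n_beads and attempts < 1000 * max(spec.n_beads, 1):
        attempts += 1
        c = np.array([
            rng.uniform(margin, spec.xy_extent - margin),
            rng.uniform(margin, spec.xy_extent - margin),
            rng.uniform(*spec.depth_range) if spec.depth_range[1] > spec.depth_range[0]
            else spec.depth_range[0],
        ])
        if all(np.linalg.norm(c - p) >= spec.min_separation for p in centers):
            centers.append(c)
    if len(centers) < spec.n_beads:
        raise ValueError("could not place beads with the required separation")

    sig_lat = fwhm_to_sigma(spec.psf.lateral_fwhm)
    sig_bead = fwhm_to_sigma(spec.bead_diameter)
    size = np.array(spec.voxel_size)
    for c in centers:
        depth = max(c[2] - vol.surface_z, 0.0)
        sig_ax = fwhm_to_sigma(spec.psf.axial_fwhm_at_depth(depth))
        s3 = np.array([np.hypot(sig_lat, sig_bead), np.hypot(sig_lat, sig_bead),
                       np.hypot(sig_ax, sig_bead)])
        loc = np.floor((c - 4 * s3) / size).astype(int)
        hic = np.ceil((c + 4 * s3) / size).astype(int) + 1
        loc = np.maximum(loc, 0)
        hic = np.minimum(hic, [vol.shape[2], vol.shape[1], vol.shape[0]])
        ax = np.arange(loc[0], hic[0]) * size[0] - c[0]
        ay = np.arange(loc[1], hic[1]) * size[1] - c[1]
        az = np.arange(loc[2], hic[2]) * size[2] - c[2]
        gx = np.exp(-0.5 * (ax / s3[0]) ** 2)
        gy = np.exp(-0.5 * (ay / s3[1]) ** 2)
        gz = np.exp(-0.5 * (az / s3[2]) ** 2)
        vol.voxels[loc[2]:hic[2], loc[1]:hic[1], loc[0]:hic[0]] += (
            spec.peak_intensity * gz[:, None, None] * gy[None, :, None]
            * gx[None, None, :])
    vol.voxels += spec.background_level
    if spec.noise_model == "gaussian":
        sigma = spec.noise_sigma or 0.05 * spec.peak_intensity
        vol.voxels = np.clip(vol.voxels + rng.normal(0, sigma, vol.shape), 0, None)

    centers = np.array(centers) if centers else np.zeros((0, 3))
    table = pd.DataFrame(centers, columns=["x_um", "y_um", "z_um"])
    table["depth_um"] = centers[:, 2] - vol.surface_z if len(centers) else []
    return vol, table


# ---------------------------------------------------------------------------
# Paired (in vivo / ex vivo) phantoms
# ---------------------------------------------------------------------------


def make_paired_phantom(spec: PhantomSpec, warp, diameter_scale_fn,
                        psf_in: PSFModel | None = None,
                        psf_ex: PSFModel | None = None,
                        n_landmarks: int = 12):
    """Build a matched in vivo / ex vivo volume pair with known truth.

    The "in vivo" volume renders ``spec`` as-is with ``psf_in`` (default:
    constant 3.4 μm axial, depth-invariant). The "ex vivo" volume maps every
    tube centerline through ``warp`` (a callable on (n, 3) μm points),
    rescales each tube's diameters with ``diameter_scale_fn`` (μm → μm), and
    renders with the depth-varying ``psf_ex`` and no attenuation, shadows or
    noise (cleared tissue, gel-filled vessels).

    Returns ``(vol_in, net_in, vol_ex, net_ex, landmarks, correspondence)``
    where landmarks is an (k, 6) array of paired points (in vivo xyz then
    ex vivo xyz, k >= 10 tube endpoints/midpoints standing in for
    bifurcation landmarks) and correspondence is an (n, 2) array of
    index-aligned ground-truth vertex pairs.
    """
    if psf_in is None:
        psf_in = PSFModel(lateral_fwhm=1.0, axial_fwhm_intercept=3.4)
    if psf_ex is None:
        psf_ex = PSFModel(lateral_fwhm=1.0, axial_fwhm_intercept=3.4,
                          axial_fwhm_slope=(7.5 - 3.4) / 1000.0)
    vol_in, net_in = render_vessel_phantom(spec, psf_in)

    ex_tubes = []
    for tube in spec.tubes:
        ex_tubes.append(TubeSpec(
            centerline=warp(tube.centerline),
            diameter=np.array([diameter_scale_fn(d) for d in tube.diameter]),
            peak_intensity=tube.peak_intensity,
            profile=tube.profile,
        ))
    ex_spec = PhantomSpec(
        volume_shape=spec.volume_shape, voxel_size=spec.voxel_size,
        tubes=ex_tubes, background_level=spec.background_level,
        noise_model="none", attenuation_length=None, shadow_regions=[],
        surface_z=spec.surface_z, origin=spec.origin,
        rng_seed=spec.rng_seed + 1,
    )
    vol_ex, net_ex = render_vessel_phantom(ex_spec, psf_ex)

    lms = []
    for tube in spec.tubes:
        pts, _, _ = _resample_polyline(tube.centerline, tube.diameter, 2.0)
        for frac in (0.0, 0.5, 1.0):
            p = pts[int(round(frac * (len(pts) - 1)))]
            lms.append(np.concatenate([p, warp(p[None, :])[0]]))
    landmarks = np.unique(np.round(np.array(lms), 9), axis=0)

    # ground-truth correspondence: the warp changes arc length, so the two
    # networks sample each tube with different vertex counts; pair vertices
    # tube-by-tube at matching arc-length fractions
    seg_in = net_in.segment_of_vertex()
    seg_ex = net_ex.segment_of_vertex()
    pairs = []
    for k in range(len(spec.tubes)):
        ids_in = np.nonzero(seg_in == k)[0]
        ids_ex = np.nonzero(seg_ex == k)[0]
        if len(ids_in) == 0 or len(ids_ex) == 0:
            continue
        frac = (np.arange(len(ids_in)) / max(len(ids_in) - 1, 1))
        j = np.round(frac * (len(ids_ex) - 1)).astype(int)
        pairs.extend(zip(ids_in, ids_ex[j]))
    corr = np.array(pairs, dtype=int)
    return vol_in, net_in, vol_ex, net_ex, landmarks, corr


# ---------------------------------------------------------------------------
# Convenience scene builders
# ---------------------------------------------------------------------------


def straight_tube_spec(diameter: float, depth: float, length: float = 60.0,
                       lateral_extent: float = 40.0,
                       voxel: float = 1.5, peak: float = 1000.0,
                       noise_model: str = "none", **kw) -> PhantomSpec:
    """A single straight horizontal tube at a given depth, in its own small
    volume (the volume's origin is placed so that the tube sits at the true
    depth below the cortical surface at z = 0)."""
    zc = depth
    z0 = zc - lateral_extent / 2.0
    nz = int(round(lateral_extent / voxel)) + 1
    ny = int(round(lateral_extent / voxel)) + 1
    nx = int(round(length / voxel)) + 1
    # The volume may extend above the cortical surface (origin z < 0) so that
    # a tube "at depth 0" is still fully contained; depth is clamped at 0
    # wherever the PSF is evaluated.
    cl = np.array([[5.0, lateral_extent / 2.0, zc],
                   [length - 5.0, lateral_extent / 2.0, zc]])
    return PhantomSpec(
        volume_shape=(nz, ny, nx), voxel_size=(voxel, voxel, voxel),
        tubes=[TubeSpec(cl, diameter, peak)],
        background_level=kw.pop("background_level", 20.0),
        noise_model=noise_model, origin=(0.0, 0.0, z0),
        surface_z=0.0, **kw,
    )


def _unit(v):
    return v / np.linalg.norm(v)


def random_vessel_spec(n_tubes: int = 20, shape_um=(200.0, 200.0, 200.0),
                       voxel: float = 1.5, diameter_range=(3.0, 12.0),
                       n_branches: int = 3, peak: float = 1000.0,
                       noise_model: str = "gaussian",
                       seed: int = 0, **kw) -> PhantomSpec:
    """A field of ``n_tubes`` gently curved, non-overlapping tubes with a few
    Y-bifurcations — the standard benchmark scene for the tracker.

    Tube diameters are drawn log-uniformly from ``diameter_range``; curvature
    is a low-amplitude sinusoidal offset; branches leave a parent tube at
    40–70° with 0.7x the parent diameter. Noise defaults to additive Gaussian
    at 5% of the tube peak (the generator-wide default).
    """
    rng = np.random.default_rng(seed)
    ex, ey, ez = shape_um
    nz, ny, nx = (int(round(e / voxel)) + 1 for e in (ez, ey, ex))
    tubes: list[TubeSpec] = []
    samples = []  # (point, radius) for separation checks

    def fine(points):
        pts, _, _ = _resample_polyline(points, np.zeros(len(points)), 2.0)
        return pts

    def far_enough(pts, diam, exempt_near=None, exempt_radius=0.0):
        if not samples:
            return True
        q = np.concatenate([s[0] for s in samples])
        rq = np.concatenate([np.full(len(s[0]), s[1]) for s in samples])
        if exempt_near is not None:
            pts = pts[np.linalg.norm(pts - exempt_near, axis=1)
                      >= exempt_radius]
            if len(pts) == 0:
                return True
        d = np.linalg.norm(pts[:, None, :] - q[None, :, :], axis=2)
        return bool(np.all(d >= diam / 2 + rq[None, :] + 4.0))

    margin = 12.0
    tries = 0
    while len(tubes) < n_tubes and tries < 400 * n_tubes:
        tries += 1
        diam = float(np.exp(rng.uniform(*np.log(diameter_range))))
        start = rng.uniform([margin] * 3, [ex - margin, ey - margin, ez - margin])
        direction = _unit(rng.normal(size=3))
        length = rng.uniform(80.0, 180.0)
        t = np.linspace(0.0, length, max(int(length / 5), 4))
        perp = _unit(np.cross(direction, rng.normal(size=3)))
        amp = rng.uniform(0.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        cl = (start[None, :] + t[:, None] * direction[None, :]
              + amp * np.sin(2 * np.pi * t / length + phase)[:, None] * perp[None, :])
        cl = cl[(cl >= margin / 2).all(axis=1)
                & (cl <= [ex - margin / 2, ey - margin / 2, ez - margin / 2]).all(axis=1)]
        if len(cl) < 4:
            continue
        if not far_enough(fine(cl), diam):
            continue
        tubes.append(TubeSpec(cl, diam, peak))
        samples.append((fine(cl), diam / 2))

    # Y-bifurcations: short obliquely leaving daughters on random parents
    for _ in range(n_branches):
        if not tubes:
            break
        parent = tubes[rng.integers(len(tubes))]
        k = rng.integers(1, len(parent.centerline) - 1)
        p0 = parent.centerline[k]
        tan = _unit(parent.centerline[k + 1] - parent.centerline[k - 1])
        perp = _unit(np.cross(tan, rng.normal(size=3)))
        ang = np.deg2rad(rng.uniform(40, 70))
        bdir = _unit(np.cos(ang) * tan + np.sin(ang) * perp)
        blen = rng.uniform(40.0, 70.0)
        t = np.linspace(0.0, blen, max(int(blen / 5), 4))
        cl = p0[None, :] + t[:, None] * bdir[None, :]
        cl = cl[(cl >= 2).all(axis=1)
                & (cl <= [ex - 2, ey - 2, ez - 2]).all(axis=1)]
        if len(cl) < 3:
            continue
        bdiam = max(float(parent.diameter[k]) * 0.7, 2.5)
        # the daughter may touch its parent near the junction but must keep
        # clear of every other tube
        pd = float(parent.diameter[k])
        if not far_enough(fine(cl), bdiam, exempt_near=p0,
                          exempt_radius=pd / 2 + bdiam / 2 + 8.0):
            continue
        tubes.append(TubeSpec(cl, bdiam, peak))

    return PhantomSpec(
        volume_shape=(nz, ny, nx), voxel_size=(voxel, voxel, voxel),
        tubes=tubes, noise_model=noise_model, rng_seed=seed + 1, **kw,
    )
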