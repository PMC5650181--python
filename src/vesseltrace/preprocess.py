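"""Image conditioning before tracking, and the axial refractive correction.

The fixed conditioning chain is: 2D Gaussian blur of each xy-plane
(FWHM 1.5 μm) → trilinear resampling to an isotropic 1.5 μm grid →
non-local-means denoising. For cleared-tissue stacks acquired through a
water-immersion objective, the apparent axial step must first be stretched
by n_agent/n_water (metadata-only; the isotropic resampling realizes the
correction on the grid, avoiding a double interpolation).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .psf_model import RefractiveScaling, axial_scale_factor, fwhm_to_sigma
from .volume import ImageVolume

__all__ = [
    "ImageVolume",
    "rescale_axial",
    "blur_xy",
    "resample_isotropic",
    "denoise_nlm",
    "standard_chain",
]


def _with_provenance(vol: ImageVolume, voxels, entry) -> ImageVolume:
    out = vol.copy(voxels)
    out.provenance.append(entry)
    return out


def rescale_axial(vol: ImageVolume, r: RefractiveScaling) -> ImageVolume:
    """Stretch the apparent axial step by n_agent/n_water (metadata only).

    Voxel data are untouched; only the z spacing (and z origin/surface
    offsets relative to the origin) change. Applying the correction twice
    is rejected via a provenance flag.
    """
    if any(p.get("op") == "rescale_axial" for p in vol.provenance):
        raise ValueError("axial rescaling already applied to this volume")
    factor = axial_scale_factor(r)
    out = vol.copy()
    sx, sy, sz = vol.voxel_size
    out.voxel_size = (sx, sy, sz * factor)
    out.provenance.append({"op": "rescale_axial", "factor": factor,
                           "n_agent": r.n_agent, "n_water": r.n_water})
    return out


def blur_xy(vol: ImageVolume, fwhm: float = 1.5) -> ImageVolume:
    """Convolve each xy-plane with an isotropic 2D Gaussian of given FWHM (μm).

    z is untouched. Borders use reflect padding.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm_to_sigma(fwhm)
    sx, sy, _ = vol.voxel_size
    blurred = ndimage.gaussian_filter(
        vol.voxels, sigma=(0.0, sigma / sy, sigma / sx), mode="reflect")
    return _with_provenance(vol, blurred, {"op": "blur_xy", "fwhm_um": fwhm})


def resample_isotropic(vol: ImageVolume, target: float = 1.5) -> ImageVolume:
    """Trilinearly resample onto an isotropic ``target``-μm grid.

    The new grid starts at the same world origin and covers the same world
    extent, so world coordinates of image features are preserved. A volume
    already on the target grid is passed through unchanged.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    sx, sy, sz = vol.voxel_size
    if np.allclose((sx, sy, sz), target):
        return _with_provenance(vol, vol.voxels.copy(),
                                {"op": "resample_isotropic", "target_um": target,
                                 "passthrough": True})
    nz, ny, nx = vol.shape
    extent = np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz])
    new_n = np.floor(extent / target + 1e-9).astype(int) + 1  # x, y, z
    zi = np.arange(new_n[2]) * target / sz
    yi = np.arange(new_n[1]) * target / sy
    xi = np.arange(new_n[0]) * target / sx
    grid = np.meshgrid(zi, yi, xi, indexing="ij")
    data = ndimage.map_coordinates(vol.voxels, [g.ravel() for g in grid],
                                   order=1, mode="nearest")
    data = data.reshape(new_n[2], new_n[1], new_n[0])
    out = ImageVolume(data, (target, target, target), vol.origin,
                      vol.surface_z, list(vol.provenance))
    out.provenance.append({"op": "resample_isotropic", "target_um": target})
    return out


def denoise_nlm(vol: ImageVolume, strength: float = 0.8) -> ImageVolume:
    """Non-local-means denoising (patch 3³, search 7³).

    The filter strength ``h`` is tied to the noise level:
    ``h = strength * sigma_est`` with ``sigma_est`` estimated from the data,
    so a noiseless volume is nearly untouched.
    """
    from skimage.restoration import denoise_nl_means, estimate_sigma

    sigma_est = float(estimate_sigma(vol.voxels))
    if sigma_est <= 0 or not np.isfinite(sigma_est):
        return _with_provenance(vol, vol.voxels.copy(),
                                {"op": "denoise_nlm", "sigma_est": 0.0})
    out = denoise_nl_means(
        vol.voxels, patch_size=3, patch_distance=3, h=strength * sigma_est,
        sigma=sigma_est, fast_mode=True, preserve_range=True)
    return _with_provenance(vol, out, {"op": "denoise_nlm",
                                       "strength": strength,
                                       "sigma_est": sigma_est})


def standard_chain(vol: ImageVolume, blur_fwhm: float = 1.5,
                   iso: float = 1.5, refractive: RefractiveScaling | None = None,
                   nlm_strength: float = 0.8) -> ImageVolume:
    """The order-fixed conditioning chain used before tracking.

    Optional axial refractive correction, then xy blur → isotropic
    resampling → non-local-means denoising. Each step appends to the
    volume's provenance record.
    """
    if refractive is not None:
        vol = rescale_axial(vol, refractive)
    return denoise_nlm(resample_isotropic(blur_xy(vol, blur_fwhm), iso),
                       nlm_strength)
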