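"""3D image volume container with world coordinates in micrometres.

Conventions used throughout the package:

* voxel arrays are indexed ``[z, y, x]`` (one TIFF page per z-plane);
* ``voxel_size`` is the ``(x, y, z)`` spacing in μm;
* world coordinates are voxel-centre positions: ``world = origin + index * size``;
* depth is measured downward from the cortical-surface plane ``z = surface_z``
  (positive below the surface).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageVolume", "trilinear"]


def trilinear(voxels: np.ndarray, pts_zyx: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate ``voxels`` at fractional index positions.

    Parameters
    ----------
    voxels : (nz, ny, nx) array
    pts_zyx : (n, 3) array of fractional indices in (z, y, x) order.
        Positions are clamped to the array border (nearest-edge padding).
    """
    pts = np.asarray(pts_zyx, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    nz, ny, nx = voxels.shape
    hi = np.array([nz - 1, ny - 1, nx - 1], dtype=float)
    p = np.clip(pts, 0.0, hi)
    i0 = np.floor(p).astype(np.intp)
    i0 = np.minimum(i0, np.maximum(voxels.shape, 2) - 2)  # keep i0+1 in bounds
    f = p - i0
    z0, y0, x0 = i0[:, 0], i0[:, 1], i0[:, 2]
    z1, y1, x1 = (np.minimum(z0 + 1, nz - 1), np.minimum(y0 + 1, ny - 1),
                  np.minimum(x0 + 1, nx - 1))
    fz, fy, fx = f[:, 0], f[:, 1], f[:, 2]
    v = voxels
    c00 = v[z0, y0, x0] * (1 - fx) + v[z0, y0, x1] * fx
    c01 = v[z0, y1, x0] * (1 - fx) + v[z0, y1, x1] * fx
    c10 = v[z1, y0, x0] * (1 - fx) + v[z1, y0, x1] * fx
    c11 = v[z1, y1, x0] * (1 - fx) + v[z1, y1, x1] * fx
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@dataclass
class ImageVolume:
    """A scalar 3D fluorescence stack with its spatial metadata.

    Attributes
    ----------
    voxels : (nz, ny, nx) float array of intensities (finite, ≥ 0).
    voxel_size : (sx, sy, sz) voxel spacing in μm.
    origin : world (x, y, z) position in μm of the centre of voxel (0, 0, 0).
    surface_z : world z of the cortical-surface plane, μm. Depth below the
        surface is ``z_world - surface_z``.
    provenance : processing history (operation names and parameters).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    surface_z: float = 0.0
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array (z, y, x)")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_extent(self) -> np.ndarray:
        """(2, 3) array of the (x, y, z) world range spanned by voxel centres."""
        nz, ny, nx = self.voxels.shape
        lo = np.array(self.origin)
        hi = lo + (np.array([nx, ny, nz]) - 1) * np.array(self.voxel_size)
        return np.stack([lo, hi])

    def world_to_index(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Map world μm points (n, 3)(x,y,z) to fractional (z, y, x) indices."""
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
        idx_xyz = (pts - np.array(self.origin)) / np.array(self.voxel_size)
        return idx_xyz[:, ::-1]

    def index_to_world(self, idx_zyx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        return idx[:, ::-1] * np.array(self.voxel_size) + np.array(self.origin)

    def depth_of(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Depth (μm) below the cortical surface for world points."""
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
        return pts[:, 2] - self.surface_z

    def interp(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Cubic-spline-interpolated intensity at world (x, y, z) μm points.

        Cardinal cubic interpolation is near-exact for the smooth (PSF-blurred)
        intensities handled here, avoiding the profile broadening a tent
        (trilinear) kernel would add. Spline coefficients are cached per
        voxel array; out-of-range points use mirror boundary values.
        """
        from scipy import ndimage

        if getattr(self, "_spline_for", None) != id(self.voxels):
            self._spline = ndimage.spline_filter(self.voxels, order=3,
                                                 mode="mirror")
            self._spline_for = id(self.voxels)
        idx = self.world_to_index(pts_xyz)
        return ndimage.map_coordinates(self._spline, idx.T, order=3,
                                       prefilter=False, mode="mirror")

    def interp_linear(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Trilinear intensity at world (x, y, z) μm points."""
        return trilinear(self.voxels, self.world_to_index(pts_xyz))

    def contains(self, pts_xyz: np.ndarray) -> np.ndarray:
        lo, hi = self.world_extent()
        pts = np.atleast_2d(np.asarray(pts_xyz, dtype=float))
        return np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)

    def copy(self, voxels: np.ndarray | None = None) -> "ImageVolume":
        return ImageVolume(
            self.voxels.copy() if voxels is None else voxels,
            self.voxel_size,
            self.origin,
            self.surface_z,
            list(self.provenance),
        )

    # -- I/O ----------------------------------------------------------------

    def save_tiff(self, path) -> None:
        """Write as a 16-bit multi-page TIFF (one page per z-plane).

        Intensities are linearly scaled into the uint16 range; the scale and
        the spatial metadata are stored in the TIFF description so that
        :func:`ImageVolume.load_tiff` round-trips.
        """
        vmax = float(self.voxels.max())
        scale = 65535.0 / vmax if vmax > 0 else 1.0
        data = np.clip(self.voxels * scale, 0, 65535).astype(np.uint16)
        meta = {
            "voxel_size_um": list(self.voxel_size),
            "origin_um": list(self.origin),
            "surface_z_um": self.surface_z,
            "intensity_scale": scale,
            "provenance": self.provenance,
        }
        tifffile.imwrite(path, data, description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path, voxel_size=None) -> "ImageVolume":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        if voxel_size is None:
            voxel_size = meta.get("voxel_size_um", (1.0, 1.0, 1.0))
        scale = meta.get("intensity_scale", 1.0)
        vol = cls(
            data.astype(float) / scale,
            tuple(voxel_size),
            tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
            float(meta.get("surface_z_um", 0.0)),
            list(meta.get("provenance", [])),
        )
        return vol
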