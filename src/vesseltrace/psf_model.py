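"""Anisotropic, depth-varying point-spread-function model and its calibration.

The two-photon PSF is approximated as an axis-aligned 3D Gaussian. In cleared
tissue imaged through a water-immersion objective, spherical aberration makes
the axial width grow (approximately linearly) with depth below the tissue
surface, while the lateral width stays flat. The model is therefore

    lateral FWHM(depth) = lateral_fwhm            (constant)
    axial   FWHM(depth) = axial_fwhm_intercept + axial_fwhm_slope * depth

Calibration follows the bead-stack procedure: sub-resolution fluorescent beads
are localized, 1D Gaussians are fitted to their intensity profiles along the
lateral and optical axes, and the per-bead FWHMs are regressed against depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .volume import ImageVolume

__all__ = [
    "FWHM_PER_SIGMA",
    "PSFModel",
    "RefractiveScaling",
    "BeadFit",
    "axial_scale_factor",
    "fit_bead_fwhm",
    "calibrate_psf_depth_model",
    "marginal_psf_covariance",
]

log = logging.getLogger(__name__)

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian — the one conversion used everywhere.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm):
    return np.asarray(fwhm, dtype=float) / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma):
    return np.asarray(sigma, dtype=float) * FWHM_PER_SIGMA


@dataclass(frozen=True)
class PSFModel:
    """Gaussian PSF with constant lateral and linearly depth-varying axial FWHM.

    Parameters are in μm; ``axial_fwhm_slope`` is μm of FWHM per μm of depth
    (0 for in vivo imaging, where the PSF does not change with depth).
    """

    lateral_fwhm: float
    axial_fwhm_intercept: float
    axial_fwhm_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.lateral_fwhm <= 0:
            raise ValueError("lateral_fwhm must be > 0")
        if self.axial_fwhm_intercept <= 0:
            raise ValueError("axial_fwhm_intercept must be > 0")

    def axial_fwhm_at_depth(self, depth) -> np.ndarray:
        """Axial FWHM (μm) at a depth (μm) below the tissue surface."""
        depth = np.asarray(depth, dtype=float)
        if np.any(depth < 0):
            raise ValueError("depth must be >= 0")
        fwhm = self.axial_fwhm_intercept + self.axial_fwhm_slope * depth
        if np.any(fwhm <= 0):
            raise ValueError("axial FWHM not positive at requested depth")
        return fwhm

    def sigmas_at_depth(self, depth):
        """(sigma_x, sigma_y, sigma_z) in μm at the given depth."""
        sl = fwhm_to_sigma(self.lateral_fwhm)
        sa = fwhm_to_sigma(self.axial_fwhm_at_depth(depth))
        return float(sl), float(sl), float(sa)

    # -- serialization (small YAML key-value file) --------------------------

    def save(self, path, refractive: "RefractiveScaling | None" = None) -> None:
        doc = {
            "lateral_fwhm_um": float(self.lateral_fwhm),
            "axial_fwhm0_um": float(self.axial_fwhm_intercept),
            "axial_slope_um_per_um": float(self.axial_fwhm_slope),
        }
        if refractive is not None:
            doc["n_agent"] = float(refractive.n_agent)
            doc["n_water"] = float(refractive.n_water)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def load(cls, path):
        """Load a PSF model (and the refractive pair, if recorded) from YAML."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        model = cls(
            lateral_fwhm=float(doc["lateral_fwhm_um"]),
            axial_fwhm_intercept=float(doc["axial_fwhm0_um"]),
            axial_fwhm_slope=float(doc.get("axial_slope_um_per_um", 0.0)),
        )
        refr = None
        if "n_agent" in doc and "n_water" in doc:
            refr = RefractiveScaling(float(doc["n_agent"]), float(doc["n_water"]))
        return model, refr


@dataclass(frozen=True)
class RefractiveScaling:
    """Refractive-index pair controlling the apparent axial step size.

    Imaging a medium of index ``n_agent`` through a water-dipped objective
    stretches the true axial sampling: the apparent z-step must be multiplied
    by ``n_agent / n_water`` to recover actual distance in the sample.
    """

    n_agent: float
    n_water: float = 1.33

    def __post_init__(self) -> None:
        if self.n_agent <= 1 or self.n_water <= 1:
            raise ValueError("refractive indices must be > 1")


def axial_scale_factor(r: RefractiveScaling) -> float:
    """Axial rescaling factor n_agent / n_water (1.49/1.33 ≈ 1.12 for SeeDB)."""
    return r.n_agent / r.n_water


@dataclass
class BeadFit:
    """Per-bead Gaussian-profile fit used for PSF calibration."""

    center: np.ndarray  # world (x, y, z), μm
    depth: float  # μm below surface
    fwhm_x: float | None = None
    fwhm_z: float | None = None
    fit_residual: float = 0.0


def _gaussian1d(x, amp, mu, sigma, baseline):
    return baseline + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _refine_center(volume: ImageVolume, center_xyz, window_vox: int = 7):
    """Refine a bead centre by intensity centre-of-mass in a small window.

    Sub-voxel centring matters: extracting a profile through an off-centre
    line biases the fitted FWHM low.
    """
    idx = volume.world_to_index(center_xyz)[0]
    lo = np.maximum(np.round(idx).astype(int) - window_vox // 2, 0)
    hi = np.minimum(lo + window_vox, volume.voxels.shape)
    lo = np.maximum(hi - window_vox, 0)
    sub = volume.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    w = sub - sub.min()
    tot = w.sum()
    if tot <= 0:
        raise ValueError("no signal near the requested bead centre")
    g = np.indices(sub.shape).reshape(3, -1)
    com = (g * w.ravel()).sum(axis=1) / tot + lo
    return volume.index_to_world(com)[0]


def fit_bead_fwhm(
    volume: ImageVolume,
    center_guess,
    axis: str,
    *,
    half_length_um: float = 12.0,
    max_residual: float = 0.15,
) -> BeadFit:
    """Fit a 1D Gaussian to a bead's intensity profile along ``axis``.

    The profile is sampled by trilinear interpolation along a line through
    the centre-of-mass-refined bead centre, parallel to the lateral (``"x"``)
    or optical (``"z"``) axis. FWHM = 2 sqrt(2 ln 2) sigma of the fit.

    Raises
    ------
    ValueError
        If there is no peak near the guess or the fit fails / has a relative
        RMS residual above ``max_residual``.
    """
    if axis not in ("x", "z"):
        raise ValueError("axis must be 'x' or 'z'")
    center = _refine_center(volume, center_guess)
    step = volume.voxel_size[0 if axis == "x" else 2]
    offsets = np.arange(-half_length_um, half_length_um + step / 2, step)
    pts = np.tile(center, (offsets.size, 1))
    pts[:, 0 if axis == "x" else 2] += offsets
    prof = volume.interp(pts)
    amp0 = prof.max() - prof.min()
    if amp0 <= 0:
        raise ValueError("flat profile: no bead peak found")
    p0 = [amp0, 0.0, 2.0, prof.min()]
    try:
        popt, _ = curve_fit(
            _gaussian1d, offsets, prof, p0=p0,
            bounds=([0, -half_length_um, 1e-3, -np.inf],
                    [np.inf, half_length_um, half_length_um, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological profiles
        raise ValueError(f"bead profile fit did not converge: {exc}") from exc
    resid = float(np.sqrt(np.mean((prof - _gaussian1d(offsets, *popt)) ** 2)) / popt[0])
    if resid > max_residual:
        raise ValueError(f"bead fit residual {resid:.3f} above {max_residual}")
    fwhm = sigma_to_fwhm(popt[2])
    depth = float(volume.depth_of(center[None, :])[0])
    fit = BeadFit(center=center, depth=depth, fit_residual=resid)
    if axis == "x":
        fit.fwhm_x = float(fwhm)
    else:
        fit.fwhm_z = float(fwhm)
    return fit


def calibrate_psf_depth_model(bead_fits, alpha: float = 0.05):
    """Fit the linear axial-FWHM-vs-depth model from per-bead fits.

    Ordinary least squares of ``fwhm_z`` against depth gives the axial
    intercept and slope (with 95% confidence intervals); OLS of ``fwhm_x``
    against depth tests whether the lateral width drifts with depth. When the
    lateral slope is not significant at ``alpha`` the lateral FWHM is taken
    as the plain mean of the bead lateral widths, otherwise the fitted line
    is reported in the summary and a warning logged.

    Returns
    -------
    (PSFModel, dict)
        The fitted model and a summary with keys ``axial_intercept``,
        ``axial_slope``, ``axial_conf_int`` (95% CI rows: intercept, slope),
        ``lateral_slope``, ``lateral_slope_pvalue``, ``lateral_significant``,
        ``n_beads``.
    """
    import statsmodels.api as sm

    fits = [f for f in bead_fits if f.fwhm_z is not None or f.fwhm_x is not None]
    depths = np.array([f.depth for f in fits])
    if len(fits) < 5 or np.unique(np.round(depths, 6)).size < 3:
        raise ValueError("need >= 5 beads spanning >= 3 distinct depths")

    zsel = [f for f in fits if f.fwhm_z is not None]
    xsel = [f for f in fits if f.fwhm_x is not None]
    if len(zsel) < 5 or len(xsel) < 5:
        raise ValueError("need >= 5 beads with both lateral and axial fits")

    dz = np.array([f.depth for f in zsel])
    fz = np.array([f.fwhm_z for f in zsel])
    res_z = sm.OLS(fz, sm.add_constant(dz)).fit()

    dx = np.array([f.depth for f in xsel])
    fx = np.array([f.fwhm_x for f in xsel])
    res_x = sm.OLS(fx, sm.add_constant(dx)).fit()
    lat_p = float(res_x.pvalues[1])
    lateral_significant = lat_p < alpha
    if lateral_significant:
        log.warning(
            "lateral FWHM drifts with depth (slope %.4g, p=%.3g); "
            "using the mean lateral FWHM anyway — inspect the bead stack",
            res_x.params[1], lat_p,
        )
    model = PSFModel(
        lateral_fwhm=float(np.mean(fx)),
        axial_fwhm_intercept=float(res_z.params[0]),
        axial_fwhm_slope=float(res_z.params[1]),
    )
    summary = {
        "axial_intercept": float(res_z.params[0]),
        "axial_slope": float(res_z.params[1]),
        "axial_conf_int": np.asarray(res_z.conf_int(alpha)),
        "lateral_mean": float(np.mean(fx)),
        "lateral_slope": float(res_x.params[1]),
        "lateral_intercept": float(res_x.params[0]),
        "lateral_slope_pvalue": lat_p,
        "lateral_significant": bool(lateral_significant),
        "n_beads": len(fits),
    }
    return model, summary


def _perpendicular_basis(tangent: np.ndarray) -> np.ndarray:
    """Rows: an orthonormal basis of the plane perpendicular to ``tangent``."""
    t = np.asarray(tangent, dtype=float)
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise ValueError("tangent must be nonzero")
    t = t / n
    # pick the world axis least aligned with t to seed the basis
    seed = np.zeros(3)
    seed[np.argmin(np.abs(t))] = 1.0
    e1 = np.cross(t, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return np.stack([e1, e2])


def marginal_psf_covariance(model: PSFModel, depth: float, tangent) -> np.ndarray:
    """2x2 covariance (μm²) of the PSF marginalized onto the plane ⟂ tangent.

    The full PSF is a zero-mean Gaussian with diagonal covariance
    diag(sigma_lat², sigma_lat², sigma_ax(depth)²). Marginalizing a Gaussian
    over the tangent direction projects its covariance onto the perpendicular
    plane: ``E Σ Eᵀ`` with E's rows an orthonormal basis of that plane.
    """
    sx, sy, sz = model.sigmas_at_depth(depth)
    t = np.asarray(tangent, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-6:
        raise ValueError("tangent must be a unit vector")
    E = _perpendicular_basis(t)
    sigma = np.diag([sx**2, sy**2, sz**2])
    return E @ sigma @ E.T
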