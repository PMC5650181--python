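"""Medial-atom vessel centerline tracking with a PSF-aware boundary model.

A vessel cross-section is modelled as an isotropic 2D Gaussian (FWHM equal
to the vessel diameter) in the plane perpendicular to the local tangent.
The imaging system convolves this with the marginal distribution of the
anisotropic (and, in cleared tissue, depth-varying) PSF in that plane; the
convolution of the two Gaussians defines an *ellipse* — the half-maximum
contour of the blurred cross-section. Eight spokes from the candidate
centre to this contour probe the image: each spoke's score is the inward
radial intensity derivative at its tip, scale-normalized by the spoke
length to the power 2·ln2 − 1. That exponent makes the per-spoke score of
a Gaussian profile peak exactly when the model's half-maximum contour
coincides with the observed one, so maximizing the summed score over radius
recovers the PSF-deconvolved vessel diameter without bias. A low score on
one spoke while the others are strong marks a potential branch.

Tracking marches bidirectionally from seed points (6-neighbour intensity
maxima above a threshold), fitting an atom every step, spawning branch
traces, ignoring seeds that fall inside already-traced vessels, and finally
pruning short free-end "hairs" produced by boundary noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .network import VesselNetwork, build_segments
from .psf_model import (PSFModel, fwhm_to_sigma, marginal_psf_covariance,
                        _perpendicular_basis)
from .volume import ImageVolume

__all__ = [
    "MedialAtom",
    "TrackerConfig",
    "BoundaryEllipse",
    "select_seeds",
    "boundary_ellipse",
    "atom_metric",
    "fit_atom",
    "trace_from_seed",
    "track_image",
    "prune_hairs",
    "recompute_diameters",
]

log = logging.getLogger(__name__)

#: Scale-normalization exponent: the spoke score  (-dI/ds) * s**GAMMA  of a
#: Gaussian profile with observed sigma_o peaks at s = sqrt(1+GAMMA)*sigma_o;
#: GAMMA = 2 ln 2 - 1 puts that peak at the observed half-maximum contour.
GAMMA = 2.0 * math.log(2.0) - 1.0

N_SPOKES = 8


@dataclass
class MedialAtom:
    """One centerline sample: position, radius, tangent, and spoke scores."""

    position: np.ndarray  # world μm (x, y, z)
    radius: float
    tangent: np.ndarray  # unit
    signal: float = 0.0
    depth: float = 0.0
    spoke_gradients: np.ndarray = field(
        default_factory=lambda: np.zeros(N_SPOKES))
    metric: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.tangent = np.asarray(self.tangent, dtype=float).reshape(3)
        n = np.linalg.norm(self.tangent)
        if n > 0:
            self.tangent = self.tangent / n


@dataclass
class TrackerConfig:
    """Tracking parameters. All lengths in μm.

    ``seed_threshold=None`` selects the threshold automatically (Otsu).
    ``hair_allowance`` is the empirical slack added to the parent radius when
    deciding whether a free-end segment is a spurious hair (default 8 μm).
    """

    psf: PSFModel
    seed_threshold: float | None = None
    step_length: float = 1.5
    radius_bounds: tuple[float, float] = (1.0, 15.0)
    branch_gradient_fraction: float = 0.6
    termination_metric_fraction: float = 0.1
    hair_allowance: float = 8.0
    min_chain_atoms: int = 3
    max_steps: int = 4000

    def __post_init__(self) -> None:
        if not (0 < self.radius_bounds[0] < self.radius_bounds[1]):
            raise ValueError("radius_bounds must be ordered and positive")
        for f in (self.branch_gradient_fraction,
                  self.termination_metric_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("fractions must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def select_seeds(vol: ImageVolume, threshold: float) -> np.ndarray:
    """Voxels above ``threshold`` that are 6-neighbour local intensity maxima.

    A voxel qualifies when it is >= each in-bounds face neighbour, with
    strict inequality against the neighbours of lower linear index (so of a
    plateau of equal maxima only the lowest-linear-index voxel seeds).
    Returns an (n, 3) integer array of (z, y, x) voxel indices.
    """
    v = vol.voxels
    ok = v > threshold
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        # neighbour on the -axis side has a lower linear index: need strict >
        ok[hi] &= v[hi] > v[lo]
        # neighbour on the +axis side has a higher linear index: >= suffices
        ok[lo] &= v[lo] >= v[hi]
    return np.argwhere(ok)


def robust_gradient_scale(vol: ImageVolume, threshold: float) -> float:
    """95th percentile of |∇I| (per μm) over voxels above ``threshold``.

    Used as the reference scale for the tracker's termination test; measured
    over foreground voxels so that sparse vessels in a dark background do
    not drag the scale to zero.
    """
    gz, gy, gx = np.gradient(vol.voxels, *(vol.voxel_size[::-1]))
    mag = np.sqrt(gx**2 + gy**2 + gz**2)
    sel = mag[vol.voxels > threshold]
    if sel.size == 0:
        sel = mag.ravel()
    return float(np.percentile(sel, 95))


# ---------------------------------------------------------------------------
# Boundary model
# ---------------------------------------------------------------------------


@dataclass
class BoundaryEllipse:
    """Half-maximum contour of the PSF-convolved vessel cross-section."""

    covariance: np.ndarray  # (2, 2) μm², in the plane basis
    basis: np.ndarray  # (2, 3) rows: orthonormal basis of the ⟂ plane
    spoke_dirs: np.ndarray  # (8, 3) unit vectors, world frame
    spoke_lengths: np.ndarray  # (8,) μm to the half-max contour

    @property
    def contour_fwhms(self) -> np.ndarray:
        """Eigen-FWHMs (μm) of the blurred cross-section, ascending."""
        ev = np.linalg.eigvalsh(self.covariance)
        return 2.0 * np.sqrt(2.0 * np.log(2.0) * ev)


def boundary_ellipse(radius: float, tangent, depth: float,
                     psf: PSFModel, extra_variance: float = 0.0) -> BoundaryEllipse:
    """Cross-section ellipse for a vessel of given radius at given depth.

    The vessel Gaussian (isotropic, FWHM = 2·radius) and the PSF marginal in
    the perpendicular plane convolve by covariance addition; spoke tips sit
    on the half-maximum contour of the result at 8 equally spaced ellipse
    parameter angles. ``extra_variance`` (μm²) adds a further isotropic
    blur to the model (used by the metric to account for grid resampling).
    """
    sv = fwhm_to_sigma(2.0 * radius)
    cov = (marginal_psf_covariance(psf, depth, tangent)
           + (sv**2 + extra_variance) * np.eye(2))
    E = _perpendicular_basis(np.asarray(tangent, dtype=float))
    # half-max contour: x' C^-1 x = 2 ln 2; spokes at 8 equally spaced plane
    # angles, each tip where its ray crosses the contour
    theta = np.arange(N_SPOKES) * (2.0 * np.pi / N_SPOKES)
    e_plane = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (8, 2)
    cinv = np.linalg.inv(cov)
    lengths = np.sqrt(2.0 * np.log(2.0)
                      / np.einsum("ij,jk,ik->i", e_plane, cinv, e_plane))
    dirs = e_plane @ E  # (8, 3) unit (E rows orthonormal)
    return BoundaryEllipse(cov, E, dirs, lengths)


def atom_metric(vol: ImageVolume, atom: MedialAtom, psf: PSFModel,
                grad_step: float | None = None):
    """Boundary-strength metric of an atom: (total, per-spoke gradients).

    per_spoke[j] is the inward radial derivative of the trilinearly
    interpolated intensity at spoke tip j (positive when intensity rises
    toward the centre). Spokes whose tips fall outside the volume contribute
    0 and are flagged. The total is the sum over spokes of
    ``max(per_spoke, 0) * spoke_length**GAMMA``.
    """
    if grad_step is None:
        grad_step = 0.5 * min(vol.voxel_size)
    # The measurement operator itself blurs the profile: trilinear
    # interpolation acts as a tent kernel (variance voxel²/6 per axis) and
    # the central difference as a box of half-width grad_step (variance
    # grad_step²/3). Folding this known variance into the model covariance
    # keeps the radius estimate unbiased on gridded data.
    grid_var = min(vol.voxel_size) ** 2 / 6.0 + grad_step**2 / 3.0
    ell = boundary_ellipse(atom.radius, atom.tangent,
                           max(atom.depth, 0.0), psf,
                           extra_variance=grid_var)
    tips = atom.position[None, :] + ell.spoke_dirs * ell.spoke_lengths[:, None]
    inner = tips - grad_step * ell.spoke_dirs
    outer = tips + grad_step * ell.spoke_dirs
    ok = vol.contains(inner) & vol.contains(outer)
    per_spoke = np.zeros(N_SPOKES)
    if np.any(ok):
        vals_in = vol.interp(inner[ok])
        vals_out = vol.interp(outer[ok])
        per_spoke[ok] = (vals_in - vals_out) / (2.0 * grad_step)
    # negative scores (intensity rising outward: the contour cuts through a
    # neighbouring bright structure) are penalized, not ignored — this keeps
    # an oversized contour from scoring well by straddling two vessels
    total = float(np.sum(per_spoke * ell.spoke_lengths**GAMMA))
    return total, per_spoke, ok


def _mean_spoke_gradient(per_spoke: np.ndarray, ok: np.ndarray) -> float:
    if ok.sum() < 3:
        return 0.0
    return float(np.clip(per_spoke[ok], 0.0, None).mean())


# ---------------------------------------------------------------------------
# Atom fitting
# ---------------------------------------------------------------------------


def _metric_at(vol, pos, radius, tangent, depth_ref, psf):
    depth = max(pos[2] - vol.surface_z, 0.0)
    a = MedialAtom(pos, radius, tangent, depth=depth)
    return atom_metric(vol, a, psf)


def _recenter_in_plane(vol, pos, radius, tangent, psf, iters: int = 4,
                       max_move: float = 3.0):
    """Iterative intensity-centroid recentring in the perpendicular plane.

    Samples the image on an ellipse-shaped window matched to the model
    cross-section, subtracts the window-edge median (local background) and
    moves to the weighted centroid. For a symmetric cross-section the fixed
    point of this map is the true centre.
    """
    E = _perpendicular_basis(tangent)
    depth = max(pos[2] - vol.surface_z, 0.0)
    ell = boundary_ellipse(radius, tangent, depth, psf)
    evals, evecs = np.linalg.eigh(ell.covariance)
    a = evecs @ np.diag(np.sqrt(evals))
    u = np.linspace(-2.2, 2.2, 13)
    uu, vv = np.meshgrid(u, u)
    plane = np.stack([uu.ravel(), vv.ravel()])  # (2, k) in sigma units
    offsets = (a @ plane).T @ E  # (k, 3) world
    rad2 = uu.ravel() ** 2 + vv.ravel() ** 2
    edge = rad2 > (2.2 * 0.85) ** 2
    total_move = 0.0
    for _ in range(iters):
        pts = pos[None, :] + offsets
        vals = vol.interp(pts)
        w = np.clip(vals - np.median(vals[edge]), 0.0, None)
        ws = w.sum()
        if ws <= 0:
            break
        centroid = (w[:, None] * pts).sum(axis=0) / ws
        move = centroid - pos
        move -= np.dot(move, tangent) * tangent  # stay in the plane
        total_move += float(np.linalg.norm(move))
        if total_move > max_move:
            break
        pos = pos + move
        if np.linalg.norm(move) < 0.01:
            break
    return pos


def _best_radius(vol, pos, tangent, psf, bounds, n_grid: int = 12) -> float:
    """Radius maximizing the metric: coarse log-spaced grid scan (the metric
    can be multimodal when the atom is off-centre or near a junction)
    followed by a bounded golden-section refinement around the best cell."""
    grid = np.geomspace(bounds[0], bounds[1], n_grid)
    vals = [_metric_at(vol, pos, r, tangent, None, psf)[0] for r in grid]
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    if hi <= lo:
        return float(grid[k])
    res = minimize_scalar(
        lambda r: -_metric_at(vol, pos, r, tangent, None, psf)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": 0.02})
    return float(res.x)


def fit_atom(vol: ImageVolume, init: MedialAtom, psf: PSFModel,
             config: TrackerConfig, rounds: int = 3,
             local_radius: bool = False,
             max_recenter: float = 3.0) -> MedialAtom:
    """Locally maximize the spoke metric over radius and in-plane position.

    Coordinate search: iterative centroid recentring in the plane
    perpendicular to the tangent, then a grid + golden-section pass over the
    radius; repeated ``rounds`` times. With ``local_radius`` the radius
    search is bracketed around ``init.radius`` (vessel calibre varies slowly
    along a chain, so marching constrains the per-step change to ±35%).
    The tangent is held fixed (it is re-estimated from neighbouring accepted
    atoms during tracing).
    """
    pos = init.position.copy()
    radius = float(np.clip(init.radius, *config.radius_bounds))
    tangent = init.tangent
    if local_radius:
        bounds = (max(radius / 1.35, config.radius_bounds[0]),
                  min(radius * 1.35, config.radius_bounds[1]))
        n_grid = 6
    else:
        bounds = config.radius_bounds
        n_grid = 12

    for _ in range(rounds):
        pos = _recenter_in_plane(vol, pos, radius, tangent, psf,
                                 max_move=max_recenter)
        radius = _best_radius(vol, pos, tangent, psf, bounds, n_grid)

    depth = max(pos[2] - vol.surface_z, 0.0)
    atom = MedialAtom(pos, radius, tangent, depth=depth)
    total, per_spoke, ok = atom_metric(vol, atom, psf)
    atom.metric = total
    atom.spoke_gradients = per_spoke
    atom.signal = float(vol.interp(pos[None, :])[0])
    atom._spoke_ok = ok
    # centre must outshine the boundary: an atom whose centre is dimmer than
    # its half-max contour is straddling a gap between structures, not a tube
    ell = boundary_ellipse(radius, tangent, depth, psf)
    tips = pos[None, :] + ell.spoke_dirs * ell.spoke_lengths[:, None]
    tin = vol.contains(tips)
    atom.tip_intensity = float(vol.interp(tips[tin]).mean()) if tin.any() else 0.0
    atom.center_ok = atom.signal > atom.tip_intensity
    if atom.center_ok:
        # the centre of a correctly fitted atom is the in-plane maximum; a
        # brighter ridge elsewhere inside the contour means the atom is
        # off-centre or straddling a neighbouring vessel
        evals, evecs = np.linalg.eigh(ell.covariance)
        a_mat = evecs @ np.diag(np.sqrt(evals))
        u = np.linspace(-1.0, 1.0, 5)
        uu, vv = np.meshgrid(u, u)
        keep = uu**2 + vv**2 <= 1.0
        plane = 1.18 * np.stack([uu[keep], vv[keep]])
        inner = pos[None, :] + (a_mat @ plane).T @ ell.basis
        iin = vol.contains(inner)
        if iin.any():
            inmax = float(vol.interp(inner[iin]).max())
            atom.center_ok = inmax <= 1.2 * max(atom.signal, 1e-12)
    return atom


def _estimate_tangent(vol: ImageVolume, pos, window_um: float = 6.0):
    """Initial tangent from the local structure tensor (smallest-eigenvalue
    eigenvector: the direction of least intensity variation)."""
    from scipy.ndimage import gaussian_filter

    idx = vol.world_to_index(pos)[0]
    w = np.ceil(window_um / np.array(vol.voxel_size[::-1])).astype(int)
    lo = np.maximum(np.round(idx).astype(int) - w, 0)
    hi = np.minimum(np.round(idx).astype(int) + w + 1, vol.voxels.shape)
    sub = gaussian_filter(vol.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
                          sigma=1.0, mode="nearest")
    if min(sub.shape) < 3:
        return np.array([1.0, 0.0, 0.0])
    gz, gy, gx = np.gradient(sub, *(vol.voxel_size[::-1]))
    g = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])
    j = g @ g.T
    evals, evecs = np.linalg.eigh(j)
    t = evecs[:, 0]
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------------
# Tracing
# ---------------------------------------------------------------------------


def _occupied(occ, vol, pos) -> bool:
    idx = np.round(vol.world_to_index(pos)[0]).astype(int)
    if np.any(idx < 0) or np.any(idx >= occ.shape):
        return True
    return bool(occ[tuple(idx)])


def _mark_occupancy(occ, vol: ImageVolume, atoms, dilate_um: float = 1.0):
    """Mark voxels within each atom's (radius + dilation) as traced."""
    size = np.array(vol.voxel_size)
    origin = np.array(vol.origin)
    nz, ny, nx = occ.shape
    for a in atoms:
        r = a.radius + dilate_um
        lo = np.maximum(np.floor((a.position - r - origin) / size).astype(int), 0)
        hi = np.minimum(np.ceil((a.position + r - origin) / size).astype(int) + 1,
                        [nx, ny, nz])
        if np.any(hi <= lo):
            continue
        ax = origin[0] + np.arange(lo[0], hi[0]) * size[0] - a.position[0]
        ay = origin[1] + np.arange(lo[1], hi[1]) * size[1] - a.position[1]
        az = origin[2] + np.arange(lo[2], hi[2]) * size[2] - a.position[2]
        ball = (az[:, None, None] ** 2 + ay[None, :, None] ** 2
                + ax[None, None, :] ** 2) <= r * r
        occ[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] |= ball


def trace_from_seed(vol: ImageVolume, seed_pos, psf: PSFModel,
                    config: TrackerConfig, occupancy,
                    term_scale: float | None = None,
                    init_tangent=None, init_radius: float = 2.5):
    """Bidirectional medial-atom march from a seed position (world μm).

    Returns ``(atoms, branch_candidates)`` — the ordered chain and a list of
    world positions just outside low-gradient spokes (potential branches) —
    or ``(None, [])`` when the seed is occupied or no atom fits. Marching
    stops on termination (metric below the fraction of the image's robust
    gradient scale), volume exit, or entry into previously traced voxels.
    """
    seed_pos = np.asarray(seed_pos, dtype=float).reshape(3)
    if _occupied(occupancy, vol, seed_pos):
        return None, []
    thr = config.seed_threshold
    if thr is None:
        from skimage.filters import threshold_otsu
        thr = float(threshold_otsu(vol.voxels))
    if term_scale is None:
        term_scale = robust_gradient_scale(vol, thr)
    term = config.termination_metric_fraction * term_scale

    tangent = (np.asarray(init_tangent, dtype=float) if init_tangent is not None
               else _estimate_tangent(vol, seed_pos))

    def acceptable(atom):
        return (atom.center_ok and atom.signal > thr and
                _mean_spoke_gradient(atom.spoke_gradients,
                                     atom._spoke_ok) >= term)

    # cheap one-round pre-fit rejects background seeds before the full fit
    seed_atom = fit_atom(vol, MedialAtom(seed_pos, init_radius, tangent),
                         psf, config, rounds=1)
    if not acceptable(seed_atom):
        return None, []
    seed_atom = fit_atom(vol, MedialAtom(seed_atom.position, seed_atom.radius,
                                         tangent), psf, config, rounds=2)
    if not acceptable(seed_atom):
        return None, []

    def march(direction):
        out = []
        pos = seed_atom.position.copy()
        radius = seed_atom.radius
        t_dir = direction.copy()
        recent = [seed_atom.signal]
        for step_i in range(config.max_steps):
            nxt = pos + config.step_length * t_dir
            if not vol.contains(nxt[None, :])[0]:
                break
            if _occupied(occupancy, vol, nxt):
                break
            if (step_i > 5 and np.linalg.norm(nxt - seed_atom.position)
                    < config.step_length / 2):
                break  # closed a loop back onto the seed
            # tight recentring cap: at junctions the centroid would otherwise
            # drag the chain toward the merged blob and deflect it
            atom = fit_atom(vol, MedialAtom(nxt, radius, t_dir), psf, config,
                            rounds=2, local_radius=True, max_recenter=1.0)
            # the centerline signal varies slowly along a vessel: a hard drop
            # relative to the chain's running level means the atom slipped
            # off the tube (e.g. into a gap between structures)
            if atom.signal < 0.3 * float(np.median(recent)):
                break
            if (not atom.center_ok or
                    _mean_spoke_gradient(atom.spoke_gradients,
                                         atom._spoke_ok) < term):
                break
            step_vec = atom.position - pos
            nstep = np.linalg.norm(step_vec)
            if nstep > 1e-9:
                new_dir = step_vec / nstep
                if np.dot(new_dir, t_dir) < 0:
                    new_dir = -new_dir
                t_dir = 0.5 * t_dir + 0.5 * new_dir  # exponential smoothing
                t_dir /= np.linalg.norm(t_dir)
            atom.tangent = t_dir.copy()
            out.append(atom)
            recent.append(atom.signal)
            if len(recent) > 10:
                recent.pop(0)
            pos = atom.position.copy()
            radius = atom.radius
        return out

    fwd = march(seed_atom.tangent.copy())
    bwd = march(-seed_atom.tangent.copy())
    atoms = list(reversed(bwd)) + [seed_atom] + fwd
    if len(atoms) < config.min_chain_atoms:
        return None, []

    # branch candidates: spokes clearly weaker than the atom's typical spoke
    # (the boundary is open where a daughter vessel leaves), plus atoms whose
    # radius jumps above the chain's running calibre (junction blobs)
    candidates = []
    chain_med_radius = float(np.median([a.radius for a in atoms]))
    for a in atoms:
        med = float(np.median(np.clip(a.spoke_gradients, 0.0, None)))
        if med <= term:
            continue
        ell = boundary_ellipse(a.radius, a.tangent, max(a.depth, 0.0), psf)
        weak = (a.spoke_gradients <
                config.branch_gradient_fraction * med)
        for j in np.nonzero(weak)[0]:
            cand = (a.position + ell.spoke_dirs[j]
                    * (ell.spoke_lengths[j] + 0.75 * a.radius))
            if vol.contains(cand[None, :])[0]:
                candidates.append(cand)
        if a.radius > 1.4 * chain_med_radius:
            candidates.append(a.position.copy())
    return atoms, candidates


def _link_chains(chains, vol, config):
    """Assemble chains into one network, connecting chain endpoints to the
    nearest vertex of another chain within a radius-aware tolerance."""
    positions, radii, tangents, signals, depths, chain_id = [], [], [], [], [], []
    edges = []
    for ci, atoms in enumerate(chains):
        base = len(positions)
        for k, a in enumerate(atoms):
            positions.append(a.position)
            radii.append(a.radius)
            tangents.append(a.tangent)
            signals.append(a.signal)
            depths.append(a.depth)
            chain_id.append(ci)
            if k > 0:
                edges.append((base + k - 1, base + k))
    if not positions:
        return VesselNetwork(np.zeros((0, 3)), np.zeros(0),
                             np.zeros((0, 2), int))
    positions = np.array(positions)
    radii = np.array(radii)
    chain_id = np.array(chain_id)
    tree = cKDTree(positions)
    starts = np.cumsum([0] + [len(c) for c in chains[:-1]])
    ends = np.cumsum([len(c) for c in chains]) - 1
    for ci, atoms in enumerate(chains):
        for vid in {starts[ci], ends[ci]}:
            tol = radii[vid] + config.step_length + 1.0
            d, idx = tree.query(positions[vid], k=min(12, len(positions)))
            for dist, j in zip(np.atleast_1d(d), np.atleast_1d(idx)):
                if chain_id[j] != ci and dist <= tol + radii[j]:
                    edges.append((vid, int(j)))
                    break
    edges = np.unique(np.sort(np.array(edges), axis=1), axis=0)
    return VesselNetwork(positions, radii, edges, np.array(tangents),
                         np.array(signals), np.array(depths))


def track_image(vol: ImageVolume, psf: PSFModel,
                config: TrackerConfig) -> VesselNetwork:
    """Trace all vessels in a (preprocessed) volume into a network.

    Seeds are processed in order of decreasing intensity; each accepted
    chain marks its interior voxels so later seeds inside it are skipped
    (which keeps runtime roughly independent of seed count). Branch
    candidates spawned by a chain are traced immediately after it. The
    assembled network is segment-decomposed and hair-pruned.
    """
    thr = config.seed_threshold
    if thr is None:
        from skimage.filters import threshold_otsu
        thr = float(threshold_otsu(vol.voxels))
    seeds_zyx = select_seeds(vol, thr)
    if len(seeds_zyx) == 0:
        log.warning("no seeds above threshold %.3g; returning empty network",
                    thr)
        return VesselNetwork(np.zeros((0, 3)), np.zeros(0),
                             np.zeros((0, 2), int))
    intensities = vol.voxels[tuple(seeds_zyx.T)]
    order = np.argsort(-intensities)
    seed_world = vol.index_to_world(seeds_zyx)[order]

    term_scale = robust_gradient_scale(vol, thr)
    occupancy = np.zeros(vol.voxels.shape, dtype=bool)
    chains = []
    for sp in seed_world:
        pending = [(sp, None)]
        while pending:
            pos, tan = pending.pop()
            atoms, cands = trace_from_seed(
                vol, pos, psf, config, occupancy,
                term_scale=term_scale, init_tangent=tan)
            if atoms is None:
                continue
            chains.append(atoms)
            _mark_occupancy(occupancy, vol, atoms)
            pending.extend((c, None) for c in cands)

    net = _link_chains(chains, vol, config)
    build_segments(net)
    return prune_hairs(net, config.hair_allowance)


# ---------------------------------------------------------------------------
# Hair pruning
# ---------------------------------------------------------------------------


def prune_hairs(net: VesselNetwork, hair_allowance: float = 8.0) -> VesselNetwork:
    """Remove spurious short free-end segments ("hairs").

    A free-end segment is removed when its arc length does not exceed the
    radius of the vessel it attaches to (taken at the junction vertex) by
    more than ``hair_allowance`` (default 8 μm). Pruning repeats to a fixed
    point; junctions left with degree 2 dissolve into their parent segment
    on the final rebuild. Paths between two junctions are never removed.
    """
    if not net.segments:
        build_segments(net)
    changed = True
    while changed:
        changed = False
        g = net.to_networkx()
        drop_edges = []
        for seg in net.segments:
            ids = seg.vertex_ids
            if len(ids) < 2:
                continue
            d0, d1 = g.degree(int(ids[0])), g.degree(int(ids[-1]))
            free, junc = None, None
            if d0 == 1 and d1 >= 3:
                free, junc = ids[0], ids[-1]
            elif d1 == 1 and d0 >= 3:
                free, junc = ids[-1], ids[0]
            else:
                continue
            parent_radius = float(net.radii[int(junc)])
            if seg.arc_length <= parent_radius + hair_allowance:
                drop_edges.extend(
                    (int(a), int(b)) for a, b in zip(ids[:-1], ids[1:]))
                changed = True
        if changed:
            drop = {frozenset(e) for e in drop_edges}
            keep = [i for i, e in enumerate(net.edges)
                    if frozenset((int(e[0]), int(e[1]))) not in drop]
            net.edges = net.edges[keep]
            build_segments(net)
    # drop isolated vertices and reindex
    used = np.zeros(net.n_vertices, dtype=bool)
    if len(net.edges):
        used[net.edges.ravel()] = True
    if not used.all():
        remap = -np.ones(net.n_vertices, dtype=int)
        remap[used] = np.arange(used.sum())
        net.positions = net.positions[used]
        net.radii = net.radii[used]
        net.tangents = net.tangents[used]
        net.signals = net.signals[used]
        net.depths = net.depths[used]
        if net.cnr is not None:
            net.cnr = net.cnr[used]
        net.edges = remap[net.edges]
        net.segments = []
        build_segments(net)
    return net


# ---------------------------------------------------------------------------
# Diameter re-measurement under an assumed PSF
# ---------------------------------------------------------------------------


def recompute_diameters(net: VesselNetwork, vol: ImageVolume,
                        psf_assumed: PSFModel,
                        radius_bounds=(1.0, 15.0)) -> VesselNetwork:
    """Re-optimize only the radius at every vertex under ``psf_assumed``.

    Positions and tangents are held fixed. Used to quantify the effect of
    ignoring the depth variation of the PSF, and to re-measure a warped
    ex vivo tree in the in vivo image (where the PSF is depth-invariant).
    Vertices outside the volume get radius NaN and are flagged in the
    returned network's ``recompute_ok`` attribute.
    """
    out = net.copy()
    inside = vol.contains(net.positions)
    ok = np.ones(net.n_vertices, dtype=bool)
    for i in range(net.n_vertices):
        if not inside[i]:
            out.radii[i] = np.nan
            ok[i] = False
            continue
        pos = net.positions[i]
        tangent = net.tangents[i]
        if np.linalg.norm(tangent) < 1e-6:
            tangent = np.array([1.0, 0.0, 0.0])
        out.radii[i] = _best_radius(vol, pos, tangent, psf_assumed,
                                    radius_bounds)
    out.recompute_ok = ok
    if out.segments:
        build_segments(out)
    return out
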