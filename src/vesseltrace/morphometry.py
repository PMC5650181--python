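"""Vessel classification and quantitative network comparison.

Implements the per-segment analyses used to compare in vivo and ex vivo
angiograms: capillary / penetrating-vessel classification, perfusion scoring
by contrast-to-noise ratio (CNR), shadow labelling beneath pial vessels,
large-vessel signal normalization, exponential signal-attenuation fitting,
and matched diameter-ratio statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import VesselNetwork, build_segments
from .volume import ImageVolume

__all__ = [
    "MorphometryConfig",
    "AttenuationFit",
    "PerfusionResult",
    "trace_penetrating_vessel",
    "classify_capillaries",
    "perfusion_cnr",
    "classify_shadowed",
    "normalize_signal",
    "fit_attenuation_length",
    "compare_diameters",
]

log = logging.getLogger(__name__)


@dataclass
class MorphometryConfig:
    """Classification thresholds (μm unless noted).

    A capillary is a non-penetrating segment with mean diameter below
    ``capillary_diameter_max`` (8 μm, the inflection point of the diameter
    histogram). Signal normalization references segments wider than
    ``normalization_diameter_min``. A segment is unperfused when more than
    ``unperfused_vertex_fraction`` of its vertices have CNR below
    ``near_zero_cnr``. Pial segments (for the shadow mask) sit shallower
    than ``pial_depth_max`` and are wider than ``pial_diameter_min``.
    """

    capillary_diameter_max: float = 8.0
    normalization_diameter_min: float = 10.0
    unperfused_vertex_fraction: float = 0.5
    near_zero_cnr: float = 1.0
    pial_depth_max: float = 50.0
    pial_diameter_min: float = 10.0
    surface_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.unperfused_vertex_fraction < 1.0):
            raise ValueError("unperfused_vertex_fraction must be in (0, 1)")
        for v in (self.capillary_diameter_max, self.normalization_diameter_min,
                  self.near_zero_cnr, self.pial_depth_max,
                  self.pial_diameter_min):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class AttenuationFit:
    """Exponential signal-vs-depth fit: signal ∝ exp(-factor·depth/length)."""

    attenuation_length: float  # μm (may be inf for non-decaying signal)
    intercept: float  # ln-signal at depth 0
    fit_window: tuple[float, float]
    stderr: float  # μm, propagated from the OLS slope
    n_points: int
    factor: float = 2.0


@dataclass
class PerfusionResult:
    vertex_cnr: np.ndarray
    segment_unperfused: np.ndarray  # bool per segment
    perfused_fraction: float
    background_mean: float
    background_std: float


# ---------------------------------------------------------------------------
# Penetrating-vessel tracing
# ---------------------------------------------------------------------------


def _incident_segments(net: VesselNetwork):
    inc = {}
    for si, seg in enumerate(net.segments):
        for end in (int(seg.vertex_ids[0]), int(seg.vertex_ids[-1])):
            inc.setdefault(end, []).append(si)
    return inc


def _segment_direction(net: VesselNetwork, si: int, from_vertex: int):
    """Unit direction of segment ``si`` leaving ``from_vertex``."""
    ids = net.segments[si].vertex_ids
    if int(ids[0]) == from_vertex:
        a, b = ids[0], ids[min(1, len(ids) - 1)]
    else:
        a, b = ids[-1], ids[max(len(ids) - 2, 0)]
    d = net.positions[int(b)] - net.positions[int(a)]
    n = np.linalg.norm(d)
    return d / n if n > 0 else d


def trace_penetrating_vessel(net: VesselNetwork, marker_vertex: int,
                             surface_normal=(0.0, 0.0, 1.0),
                             label: str = "penetrating-artery"):
    """Trace a penetrating vessel downward from a near-surface marker.

    From the marker's segment the walk proceeds in the direction of the
    surface normal (pointing into the tissue). At every junction it follows
    the outgoing segment whose local direction makes the smallest angle
    with the normal, and it stops at a free end (a segment end not connected
    to anything below). All traversed segments are labelled ``label``.

    Returns the ordered list of segment indices.
    """
    if not net.segments:
        build_segments(net)
    normal = np.asarray(surface_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    inc = _incident_segments(net)

    start_si = None
    for si, seg in enumerate(net.segments):
        if marker_vertex in seg.vertex_ids:
            start_si = si
            break
    if start_si is None:
        raise ValueError(f"marker vertex {marker_vertex} is not on the network")

    # orient the first segment downward: exit by the deeper end
    seg = net.segments[start_si]
    e0, e1 = int(seg.vertex_ids[0]), int(seg.vertex_ids[-1])
    exit_vertex = e1 if (net.positions[e1] - net.positions[e0]) @ normal >= 0 else e0

    path = [start_si]
    visited = {start_si}
    while True:
        candidates = [si for si in inc.get(exit_vertex, [])
                      if si not in visited]
        if not candidates:
            break  # free end: nothing below
        angles = []
        for si in candidates:
            d = _segment_direction(net, si, exit_vertex)
            cosang = float(np.clip(d @ normal, -1.0, 1.0))
            angles.append(np.arccos(cosang))
        best = candidates[int(np.argmin(angles))]
        path.append(best)
        visited.add(best)
        seg = net.segments[best]
        e0, e1 = int(seg.vertex_ids[0]), int(seg.vertex_ids[-1])
        exit_vertex = e1 if e0 == exit_vertex else e0
    for si in path:
        net.segments[si].class_label = label
    return path


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_capillaries(net: VesselNetwork,
                         config: MorphometryConfig | None = None) -> VesselNetwork:
    """Label every unlabelled segment with mean diameter < 8 μm 'capillary'.

    Penetrating labels take precedence: a narrow segment on a penetrating
    path stays penetrating.
    """
    config = config or MorphometryConfig()
    if not net.segments:
        build_segments(net)
    for seg in net.segments:
        if seg.class_label == "unset" and \
                seg.mean_diameter < config.capillary_diameter_max:
            seg.class_label = "capillary"
    return net


def perfusion_cnr(net: VesselNetwork, vol: ImageVolume,
                  background_threshold: float,
                  config: MorphometryConfig | None = None) -> PerfusionResult:
    """Score gel perfusion per segment from vertex CNR in ``vol``.

    Background voxels are those below ``background_threshold``. Each vertex's
    CNR is (signal − mean background) / std(background), the signal being the
    image intensity at the (registered) vertex position. A segment is
    unperfused when more than half (configurable) of its vertices have CNR
    below ``near_zero_cnr``. Flags are invariant to affine intensity
    rescaling provided the threshold is transformed consistently.
    """
    config = config or MorphometryConfig()
    if not net.segments:
        build_segments(net)
    bg = vol.voxels[vol.voxels < background_threshold]
    if bg.size == 0:
        raise ValueError("no voxels below the background threshold")
    mu, sd = float(bg.mean()), float(bg.std())
    if sd == 0:
        raise ValueError("degenerate background (zero variance)")
    sig = vol.interp(net.positions)
    cnr = (sig - mu) / sd
    net.cnr = cnr
    flags = np.zeros(len(net.segments), dtype=bool)
    for i, seg in enumerate(net.segments):
        frac = float((cnr[seg.vertex_ids] < config.near_zero_cnr).mean())
        flags[i] = frac > config.unperfused_vertex_fraction
        seg.unperfused = bool(flags[i])
    fraction = 1.0 - flags.sum() / len(flags) if len(flags) else 1.0
    return PerfusionResult(cnr, flags, float(fraction), mu, sd)


def build_pial_mask(net: VesselNetwork, config: MorphometryConfig | None = None):
    """Union of xy-projected pial segments dilated by their radii (shapely)."""
    import shapely
    from shapely.ops import unary_union

    config = config or MorphometryConfig()
    geoms = []
    for seg in net.segments:
        depths = net.depths[seg.vertex_ids]
        if (np.mean(depths) < config.pial_depth_max
                and seg.mean_diameter > config.pial_diameter_min):
            xy = net.positions[seg.vertex_ids][:, :2]
            if len(xy) >= 2:
                geoms.append(shapely.LineString(xy).buffer(seg.mean_radius))
            else:
                geoms.append(shapely.Point(xy[0]).buffer(seg.mean_radius))
    return unary_union(geoms) if geoms else shapely.Polygon()


def classify_shadowed(net: VesselNetwork, pial_mask_xy=None,
                      config: MorphometryConfig | None = None):
    """Label vertices/segments lying directly beneath pial vessels.

    ``pial_mask_xy`` may be any shapely geometry in world xy μm; when None
    it is built from the network's own pial segments (shallow, wide),
    dilated by their radii and projected to the xy-plane. A vertex is
    shadowed iff its (x, y) falls inside the mask; segments take the
    majority vote of their vertices.

    Returns (network, per-vertex boolean array).
    """
    import shapely

    config = config or MorphometryConfig()
    if not net.segments:
        build_segments(net)
    if pial_mask_xy is None:
        pial_mask_xy = build_pial_mask(net, config)
    flags = shapely.contains_xy(pial_mask_xy, net.positions[:, 0],
                                net.positions[:, 1])
    for seg in net.segments:
        seg.shadowed = bool(flags[seg.vertex_ids].mean() > 0.5)
    return net, np.asarray(flags, dtype=bool)


def normalize_signal(net: VesselNetwork,
                     config: MorphometryConfig | None = None) -> VesselNetwork:
    """Normalize segment signals to the mean of large (> 10 μm) vessels.

    The mean of the mean signals over qualifying segments is given the
    arbitrary value 1 and every segment's signal is expressed relative to
    it (vertex signals are divided by the same constant).
    """
    config = config or MorphometryConfig()
    if not net.segments:
        build_segments(net)
    ref = [seg.mean_signal for seg in net.segments
           if seg.mean_diameter > config.normalization_diameter_min]
    if not ref:
        raise ValueError("no segment exceeds the normalization diameter")
    scale = float(np.mean(ref))
    if scale <= 0:
        raise ValueError("non-positive reference signal")
    net.signals = net.signals / scale
    for seg in net.segments:
        seg.mean_signal /= scale
    return net


def fit_attenuation_length(depths, signals, fit_window,
                           factor: float = 2.0) -> AttenuationFit:
    """Characteristic attenuation length from signal-vs-depth pairs.

    Ordinary least squares of ln(signal) against depth over the window;
    the length ℓ is defined by signal ∝ exp(−factor·depth/ℓ). The default
    ``factor=2`` is the two-photon convention (detected fluorescence decays
    at twice the excitation attenuation rate); pass 1 for the single-pass
    convention. Non-positive signals in the window are excluded with a
    warning; a non-decaying fit reports ℓ = inf.
    """
    import statsmodels.api as sm

    depths = np.asarray(depths, dtype=float)
    signals = np.asarray(signals, dtype=float)
    lo, hi = fit_window
    sel = (depths >= lo) & (depths <= hi)
    if np.any(signals[sel] <= 0):
        log.warning("excluding %d non-positive signals from attenuation fit",
                    int((signals[sel] <= 0).sum()))
        sel &= signals > 0
    d, s = depths[sel], signals[sel]
    if d.size < 10:
        raise ValueError("need at least 10 points spanning the fit window")
    res = sm.OLS(np.log(s), sm.add_constant(d)).fit()
    slope = float(res.params[1])
    se_slope = float(res.bse[1])
    if slope >= 0:
        log.warning("signal does not decay with depth; attenuation length inf")
        return AttenuationFit(np.inf, float(res.params[0]), (lo, hi),
                              np.inf, d.size, factor)
    ell = -factor / slope
    stderr = factor * se_slope / slope**2
    return AttenuationFit(float(ell), float(res.params[0]), (lo, hi),
                          float(stderr), d.size, factor)


def compare_diameters(match_table: pd.DataFrame, net_in: VesselNetwork,
                      net_ex: VesselNetwork, min_matched: int = 3):
    """Matched ex-vivo/in-vivo diameter ratios, aggregated per in vivo segment.

    ``match_table`` holds vertex correspondences (columns ``id_a`` = in vivo,
    ``id_b`` = ex vivo, from :func:`vesseltrace.network.match_vertices` with
    both networks in the same space; the ex vivo radii are expected to have
    been re-measured in that space). For each in vivo segment with at least
    ``min_matched`` matched vertices the ratio is
    mean(ex radii of partners) / mean(in radii of matched vertices).

    Returns (per-segment DataFrame, summary dict, unmatched segment ids).
    Summary keys: ``mean_ratio_by_class``, ``fraction_capillaries_larger_in_vivo``,
    ``diameter_mean_sd_by_class``, ``n_segments_compared``.
    """
    if match_table is None or len(match_table) == 0:
        raise ValueError("empty vertex correspondence")
    if not net_in.segments:
        build_segments(net_in)
    partner = dict(zip(match_table["id_a"].astype(int),
                       match_table["id_b"].astype(int)))
    rows, unmatched = [], []
    for si, seg in enumerate(net_in.segments):
        ids = [int(v) for v in seg.vertex_ids if int(v) in partner]
        if len(ids) < min_matched:
            unmatched.append(si)
            continue
        r_in = float(np.nanmean(net_in.radii[ids]))
        r_ex = float(np.nanmean(net_ex.radii[[partner[v] for v in ids]]))
        if not (np.isfinite(r_in) and np.isfinite(r_ex)) or r_in <= 0:
            unmatched.append(si)
            continue
        rows.append({
            "segment": si,
            "class_label": seg.class_label,
            "diameter_in_um": 2 * r_in,
            "diameter_ex_um": 2 * r_ex,
            "ratio_ex_in": r_ex / r_in,
            "n_matched_vertices": len(ids),
        })
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("no segment had enough matched vertices")
    by_class = table.groupby("class_label")
    caps = table[table["class_label"] == "capillary"]
    summary = {
        "mean_ratio_by_class": by_class["ratio_ex_in"].mean().to_dict(),
        "fraction_capillaries_larger_in_vivo": (
            float((caps["ratio_ex_in"] < 1.0).mean()) if len(caps) else np.nan),
        "diameter_mean_sd_by_class": {
            k: (float(g["diameter_in_um"].mean()),
                float(g["diameter_in_um"].std(ddof=1)) if len(g) > 1 else 0.0)
            for k, g in by_class},
        "n_segments_compared": int(len(table)),
    }
    return table, summary, unmatched
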