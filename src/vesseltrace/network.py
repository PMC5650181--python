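"""Vessel network graph model, segment decomposition, and TPS registration.

A traced vasculature is a graph whose vertices are centerline samples
(medial atoms: position, radius, tangent, local image signal) and whose
edges connect consecutive samples. A *segment* is a maximal path between
junctions and/or free ends — every interior vertex of a segment has degree 2.

Networks from two image spaces (in vivo / ex vivo) are aligned with an
interpolating 3D thin-plate spline fitted to manually identified landmark
pairs (vascular branch points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VesselNetwork",
    "VesselSegment",
    "TPSTransform",
    "build_segments",
    "fit_tps",
    "inverse_transform_from_landmarks",
    "apply_transform",
    "match_vertices",
    "read_network",
    "write_network",
    "read_landmarks",
    "write_landmarks",
]


@dataclass
class VesselSegment:
    """A maximal vessel path between junctions and/or free ends."""

    vertex_ids: np.ndarray  # ordered
    arc_length: float = 0.0
    mean_radius: float = 0.0
    mean_signal: float = 0.0
    class_label: str = "unset"  # capillary | penetrating-artery | penetrating-venule | pial | other | unset
    shadowed: bool = False
    unperfused: bool = False

    @property
    def mean_diameter(self) -> float:
        return 2.0 * self.mean_radius


@dataclass
class VesselNetwork:
    """Graph of medial-atom vertices with per-vertex geometry and signal."""

    positions: np.ndarray  # (n, 3) world μm (x, y, z)
    radii: np.ndarray  # (n,)
    edges: np.ndarray  # (m, 2) int vertex ids
    tangents: np.ndarray | None = None  # (n, 3) unit
    signals: np.ndarray | None = None  # (n,)
    depths: np.ndarray | None = None  # (n,) μm below surface
    cnr: np.ndarray | None = None  # (n,)
    segments: list[VesselSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(self.edges) and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loop edges are not allowed")
        if self.tangents is None:
            self.tangents = np.zeros((n, 3))
        else:
            self.tangents = np.asarray(self.tangents, dtype=float).reshape(n, 3)
        self.signals = (np.zeros(n) if self.signals is None
                        else np.asarray(self.signals, dtype=float).reshape(n))
        self.depths = (self.positions[:, 2].copy() if self.depths is None
                       else np.asarray(self.depths, dtype=float).reshape(n))

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def total_edge_length(self) -> float:
        if len(self.edges) == 0:
            return 0.0
        d = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).sum())

    def segment_of_vertex(self) -> np.ndarray:
        """Per-vertex segment index (junction vertices get the last segment
        that contains them; -1 where unassigned)."""
        out = np.full(self.n_vertices, -1, dtype=int)
        for i, seg in enumerate(self.segments):
            out[seg.vertex_ids] = i
        return out

    def copy(self) -> "VesselNetwork":
        net = VesselNetwork(
            self.positions.copy(), self.radii.copy(), self.edges.copy(),
            self.tangents.copy(), self.signals.copy(), self.depths.copy(),
            None if self.cnr is None else self.cnr.copy(),
        )
        net.segments = [VesselSegment(s.vertex_ids.copy(), s.arc_length,
                                      s.mean_radius, s.mean_signal,
                                      s.class_label, s.shadowed, s.unperfused)
                        for s in self.segments]
        return net


def _segment_stats(net: VesselNetwork, seg: VesselSegment) -> None:
    ids = seg.vertex_ids
    pos = net.positions[ids]
    seg.arc_length = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    seg.mean_radius = float(net.radii[ids].mean())
    seg.mean_signal = float(net.signals[ids].mean())


def build_segments(net: VesselNetwork) -> VesselNetwork:
    """Partition the edge set into maximal degree-2-interior paths.

    Idempotent; every edge ends up in exactly one segment. Cycles whose
    vertices are all degree 2 (capillary loops) become a single closed
    segment starting at an arbitrary vertex.
    """
    g = net.to_networkx()
    existing_labels = {}
    for seg in net.segments:
        key = frozenset(seg.vertex_ids.tolist())
        existing_labels[key] = seg
    net.segments = []
    visited = set()  # undirected edges as frozensets

    def walk(start, nxt):
        path = [start, nxt]
        visited.add(frozenset((start, nxt)))
        while g.degree(path[-1]) == 2:
            a, b = g.neighbors(path[-1])
            nxt2 = b if a == path[-2] else a
            e = frozenset((path[-1], nxt2))
            if e in visited:
                break
            visited.add(e)
            path.append(nxt2)
        return path

    terminals = [v for v in g.nodes if g.degree(v) != 2 and g.degree(v) > 0]
    for t in terminals:
        for nb in g.neighbors(t):
            e = frozenset((t, nb))
            if e not in visited:
                net.segments.append(VesselSegment(np.array(walk(t, nb))))
    # pure cycles (all vertices degree 2)
    for v in g.nodes:
        for nb in g.neighbors(v):
            e = frozenset((v, nb))
            if e not in visited:
                net.segments.append(VesselSegment(np.array(walk(v, nb))))
    for seg in net.segments:
        _segment_stats(net, seg)
        prev = existing_labels.get(frozenset(seg.vertex_ids.tolist()))
        if prev is not None:  # keep labels across a rebuild
            seg.class_label = prev.class_label
            seg.shadowed = prev.shadowed
            seg.unperfused = prev.unperfused
    return net


# ---------------------------------------------------------------------------
# Thin-plate splines (3D polyharmonic, kernel U(r) = r)
# ---------------------------------------------------------------------------


@dataclass
class TPSTransform:
    """Interpolating 3D thin-plate spline fitted to landmark pairs.

    f(x) = A [1, x] + sum_i w_i * |x - s_i|   (per output coordinate)

    The bordered linear system enforces the side conditions sum(w) = 0 and
    sum(w_i s_i) = 0, so the transform is exactly affine when the landmark
    correspondence is affine (zero bending).
    """

    source: np.ndarray  # (n, 3)
    affine: np.ndarray  # (4, 3): rows constant, x, y, z
    weights: np.ndarray  # (n, 3)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        r = np.sqrt(((pts[:, None, :] - self.source[None, :, :]) ** 2).sum(-1))
        p = np.hstack([np.ones((len(pts), 1)), pts])
        return p @ self.affine + r @ self.weights

    def bending_weight_norm(self) -> float:
        return float(np.abs(self.weights).max()) if len(self.weights) else 0.0


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSTransform:
    """Fit an interpolating 3D TPS mapping source landmarks onto targets.

    Requires ≥ 5 non-coplanar source landmarks (coplanar configurations make
    the affine part ill-determined and are rejected).
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    dst = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(src)
    if n < 5:
        raise ValueError("need at least 5 landmark pairs")
    if len(np.unique(np.round(src, 9), axis=0)) < n:
        raise ValueError("duplicate source landmarks")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("landmarks are coplanar or degenerate; "
                         "cannot determine a 3D thin-plate spline")
    k = np.sqrt(((src[:, None, :] - src[None, :, :]) ** 2).sum(-1))
    p = np.hstack([np.ones((n, 1)), src])
    sys_mat = np.zeros((n + 4, n + 4))
    sys_mat[:n, :n] = k
    sys_mat[:n, n:] = p
    sys_mat[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    sol = np.linalg.solve(sys_mat, rhs)
    return TPSTransform(source=src.copy(), affine=sol[n:], weights=sol[:n])


def inverse_transform_from_landmarks(source, target) -> TPSTransform:
    """Practical TPS inverse: fit the reverse direction on swapped pairs.

    A TPS has no closed-form inverse; fitting target→source is exact at the
    landmarks and accurate inside the landmark hull for smooth warps.
    """
    return fit_tps(target, source)


def _retangent(net: VesselNetwork) -> None:
    """Re-derive vertex tangents from positions along each segment."""
    if not net.segments:
        build_segments(net)
    for seg in net.segments:
        ids = seg.vertex_ids
        if len(ids) < 2:
            continue
        pos = net.positions[ids]
        d = np.gradient(pos, axis=0)
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        net.tangents[ids] = d / nrm


def apply_transform(net: VesselNetwork, t: TPSTransform) -> VesselNetwork:
    """Map vertex positions through ``t``; topology, radii, signal unchanged.

    Radii are *not* rescaled by the warp: per the comparison protocol they
    must be re-measured in the target image (see
    :func:`vesseltrace.tracking.recompute_diameters`). Tangents are
    re-derived from the mapped positions.
    """
    out = net.copy()
    out.positions = t(net.positions)
    _retangent(out)
    build_segments(out)
    return out


def match_vertices(net_a: VesselNetwork, net_b: VesselNetwork, radius: float = 3.0):
    """Mutual-nearest-neighbour vertex correspondence within ``radius`` μm.

    Returns a DataFrame with columns ``id_a, id_b, distance`` plus lists of
    unmatched vertex ids for each network. Mutuality avoids many-to-one
    collapse where the two tracings sample the centerline differently.
    """
    ta, tb = cKDTree(net_a.positions), cKDTree(net_b.positions)
    d_ab, j_ab = tb.query(net_a.positions, distance_upper_bound=radius)
    d_ba, j_ba = ta.query(net_b.positions, distance_upper_bound=radius)
    rows = []
    for i in range(net_a.n_vertices):
        j = j_ab[i]
        if j < net_b.n_vertices and j_ba[j] == i:
            rows.append((i, int(j), float(d_ab[i])))
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "distance"])
    unmatched_a = sorted(set(range(net_a.n_vertices)) - set(table["id_a"]))
    unmatched_b = sorted(set(range(net_b.n_vertices)) - set(table["id_b"]))
    return table, unmatched_a, unmatched_b


# ---------------------------------------------------------------------------
# I/O: tab-separated network files, comma-separated landmark files
# ---------------------------------------------------------------------------

_VERTEX_COLS = ["id", "x_um", "y_um", "z_um", "radius_um",
                "tangent_x", "tangent_y", "tangent_z",
                "signal", "depth_um", "segment_id"]


def write_network(net: VesselNetwork, path) -> None:
    """Write a network as a documented tab-separated file.

    Layout: comment header, a ``[vertices]`` block (one row per vertex:
    id, world position μm, radius μm, unit tangent, signal, depth μm,
    segment id) and an ``[edges]`` block (vertex id pairs). Round-trips
    losslessly at 17-significant-digit precision.
    """
    seg_of = net.segment_of_vertex()
    with open(path, "w") as fh:
        fh.write("# vesseltrace network: positions/radii in um; depth below "
                 "cortical surface\n")
        fh.write("[vertices]\n")
        fh.write("\t".join(_VERTEX_COLS) + "\n")
        for i in range(net.n_vertices):
            row = [str(i)] + [format(v, ".17g") for v in (
                net.positions[i, 0], net.positions[i, 1], net.positions[i, 2],
                net.radii[i], net.tangents[i, 0], net.tangents[i, 1],
                net.tangents[i, 2], net.signals[i], net.depths[i])]
            row.append(str(seg_of[i]))
            fh.write("\t".join(row) + "\n")
        fh.write("[edges]\n")
        fh.write("id_a\tid_b\n")
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")


def read_network(path) -> VesselNetwork:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    iv = lines.index("[vertices]")
    ie = lines.index("[edges]")
    vrows = [ln.split("\t") for ln in lines[iv + 2:ie]]
    erows = [ln.split("\t") for ln in lines[ie + 2:]]
    if not vrows:
        return VesselNetwork(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2), int))
    v = np.array([[float(c) for c in row] for row in vrows])
    order = np.argsort(v[:, 0])
    v = v[order]
    edges = (np.array([[int(a), int(b)] for a, b in erows])
             if erows else np.zeros((0, 2), int))
    net = VesselNetwork(
        positions=v[:, 1:4], radii=v[:, 4], edges=edges,
        tangents=v[:, 5:8], signals=v[:, 8], depths=v[:, 9],
    )
    build_segments(net)
    return net


def write_landmarks(path, pts_in: np.ndarray, pts_ex: np.ndarray) -> None:
    """Comma-separated landmark pairs, in vivo coordinates first (μm)."""
    df = pd.DataFrame(
        np.hstack([np.atleast_2d(pts_in), np.atleast_2d(pts_ex)]),
        columns=["x_in", "y_in", "z_in", "x_ex", "y_ex", "z_ex"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_landmarks(path):
    df = pd.read_csv(path)
    return df[["x_in", "y_in", "z_in"]].to_numpy(), df[["x_ex", "y_ex", "z_ex"]].to_numpy()
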