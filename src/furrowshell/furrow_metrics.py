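"""Morphometric quantifications on simulated trajectories and synthetic tracks.

Implements the measurement procedures used to characterise furrow formation:
signed three-point (circumcircle) curvature on planar sections, AP/DV ventral
midline curvature series along the pre-strain ramp, buckling-threshold
detection, furrow apex depth at AP stations, apical-to-vitelline distance
maps, pole displacement, tissue shortening along surface sections, and
local-regression (LOESS-style) smoothing and derivatives for recoil traces.

Sign convention for curvature: convex (outward-bulging) curvature is
positive, concave negative; kappa = 1/R of the circle through three points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .geometry import EmbryoMesh, VitellineSurface
from .shell_solver import SolverState, Trajectory

__all__ = [
    "MidlineSection",
    "CurvatureSeries",
    "three_point_curvature",
    "extract_section",
    "midline_curvature",
    "buckling_threshold",
    "furrow_apex_depth",
    "distance_map_to_vitelline",
    "pole_displacement",
    "tissue_shortening",
    "recoil_velocity",
    "loess_fit",
]


# --------------------------------------------------------------------------- #
# sections
# --------------------------------------------------------------------------- #
@dataclass
class MidlineSection:
    """Ordered planar contour from a plane-mesh intersection."""

    points: np.ndarray  # (N, 2) ordered along the closed contour
    points3d: np.ndarray  # (N, 3)
    plane: str  # "sagittal" or "cross"
    station: float  # AP coordinate of a cross section (0 for sagittal)

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("section needs at least 3 points")

    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _stitch_segments(segments: np.ndarray) -> np.ndarray:
    """Order intersection segments into a single closed polyline."""
    n = len(segments)
    pts = segments.reshape(-1, 3)
    # merge coincident endpoints by rounding
    key = np.round(pts / 1e-9).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    ends = inv.reshape(n, 2)
    # adjacency between segment endpoints
    from collections import defaultdict

    at_node = defaultdict(list)
    for i, (a, b) in enumerate(ends):
        at_node[a].append(i)
        at_node[b].append(i)
    used = np.zeros(n, dtype=bool)
    order = [0]
    used[0] = True
    node = ends[0, 1]
    chain = [ends[0, 0], node]
    while True:
        nxt = [j for j in at_node[node] if not used[j]]
        if not nxt:
            break
        j = nxt[0]
        used[j] = True
        a, b = ends[j]
        node = b if a == node else a
        chain.append(node)
        order.append(j)
    # recover coordinates of chained nodes
    coord_of = {}
    for i, (a, b) in enumerate(ends):
        coord_of[a] = segments[i, 0]
        coord_of[b] = segments[i, 1]
    poly = np.array([coord_of[c] for c in chain[:-1]])  # closed: drop repeat
    return poly


def extract_section(
    vertices: np.ndarray,
    faces: np.ndarray,
    plane: str = "cross",
    station: float = 0.0,
) -> MidlineSection:
    """Planar section of a (possibly deformed) configuration.

    ``plane='cross'`` cuts at x = station with in-plane coordinates (y, z);
    ``plane='sagittal'`` cuts at y = 0 with in-plane coordinates (x, z).
    """
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if plane == "cross":
        normal, origin = np.array([1.0, 0, 0]), np.array([station, 0.0, 0.0])
        cols = (1, 2)
    elif plane == "sagittal":
        normal, origin = np.array([0.0, 1.0, 0]), np.array([0.0, station, 0.0])
        cols = (0, 2)
    else:
        raise ValueError("plane must be 'cross' or 'sagittal'")
    segments = trimesh.intersections.mesh_plane(tm, normal, origin)
    if len(segments) < 3:
        raise ValueError(f"section plane {plane} at {station} misses the mesh")
    poly3 = _stitch_segments(np.asarray(segments))
    return MidlineSection(
        points=poly3[:, cols], points3d=poly3, plane=plane, station=station
    )


# --------------------------------------------------------------------------- #
# curvature
# --------------------------------------------------------------------------- #
def three_point_curvature(p1, p2, p3, outward=None) -> float:
    """Signed curvature 1/R of the circle through three planar points.

    ``outward`` is a 2D direction indicating the outward side at the middle
    point; the curvature is positive when the triple bulges outward (convex)
    and negative when it bows inward (concave).  Collinear points give 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if min(a, b, c) == 0.0:
        raise ValueError("coincident points have no circumcircle")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    kappa = 2.0 * abs(cross) / (a * b * c)
    if kappa == 0.0:
        return 0.0
    if outward is None:
        return kappa
    bulge = p2 - 0.5 * (p1 + p3)
    sign = 1.0 if float(np.dot(bulge, np.asarray(outward, dtype=float))) >= 0 else -1.0
    return sign * kappa


@dataclass
class CurvatureSeries:
    """Ventral-midline curvature along a ramp (or time) axis."""

    control: np.ndarray  # eps_midline (or time) per state
    kappa: np.ndarray
    axis: str  # "AP" or "DV"


def _ventral_apex(section: MidlineSection):
    """Interpolated ventral (z < 0) contour point at in-plane abscissa 0."""
    pts = np.vstack([section.points, section.points[:1]])
    out = None
    for i in range(len(pts) - 1):
        u, v = pts[i], pts[i + 1]
        if min(u[1], v[1]) > 0:  # dorsal side
            continue
        if u[0] == 0.0 and u[1] < 0:
            cand = u
        elif (u[0] < 0) != (v[0] < 0):
            w = -u[0] / (v[0] - u[0])
            cand = u + w * (v - u)
            if cand[1] > 0:
                continue
        else:
            continue
        if out is None or cand[1] < out[1]:
            out = cand
    if out is None:
        raise ValueError("section does not cross the ventral midline")
    return out


def _curvature_at_apex(section: MidlineSection, spacing: float) -> float:
    """Three-point curvature at the ventral apex with arc spacing ``spacing``."""
    pts = section.points
    s = section.arclength()
    apex = _ventral_apex(section)
    # closest polyline node to the apex
    i0 = int(np.argmin(np.linalg.norm(pts - apex, axis=1)))
    total = s[-1] + np.linalg.norm(pts[-1] - pts[0])

    def at_arc(ds):
        target = (s[i0] + ds) % total
        return np.array(
            [np.interp(target, s, pts[:, 0]), np.interp(target, s, pts[:, 1])]
        )

    p1, p2, p3 = at_arc(-spacing), pts[i0], at_arc(spacing)
    return three_point_curvature(p1, p2, p3, outward=np.array([0.0, -1.0]))


def _default_spacing(mesh: EmbryoMesh, n_edges: float = 3.0) -> float:
    mean_edge = np.sqrt(4.0 * mesh.reference_area.mean() / np.sqrt(3.0))
    return n_edges * mean_edge


def midline_curvature(
    trajectory: Trajectory,
    axis: str = "DV",
    spacing: float | None = None,
    station: float = 0.0,
) -> CurvatureSeries:
    """Ventral midline curvature per ramp state.

    ``axis='AP'`` measures on the mid-sagittal section (curvature of the AP
    midline); ``axis='DV'`` on the cross section at ``station``.
    """
    if axis not in ("AP", "DV"):
        raise ValueError("axis must be 'AP' or 'DV'")
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    mesh = trajectory.mesh
    spacing = spacing if spacing is not None else _default_spacing(mesh)
    plane = "sagittal" if axis == "AP" else "cross"
    kappas, controls = [], []
    for st in trajectory.states:
        sec = extract_section(st.positions, mesh.faces, plane=plane, station=station if plane == "cross" else 0.0)
        kappas.append(_curvature_at_apex(sec, spacing))
        controls.append(st.eps_midline)
    return CurvatureSeries(
        control=np.asarray(controls), kappa=np.asarray(kappas), axis=axis
    )


def buckling_threshold(series: CurvatureSeries) -> float | None:
    """First control value at which the curvature reaches zero or below.

    Linear interpolation between ramp steps; returns ``None`` when the
    curvature stays positive over the whole ramp ("threshold not reached").
    """
    k, c = np.asarray(series.kappa), np.asarray(series.control)
    below = np.nonzero(k <= 0.0)[0]
    if len(below) == 0:
        return None
    j = below[0]
    if j == 0:
        return float(c[0])
    return float(c[j - 1] + (0.0 - k[j - 1]) * (c[j] - c[j - 1]) / (k[j] - k[j - 1]))


# --------------------------------------------------------------------------- #
# furrow depth, distances, shortening
# --------------------------------------------------------------------------- #
def furrow_apex_depth(trajectory: Trajectory, ap_stations) -> pd.DataFrame:
    """Inward offset of the ventral midline from its reference height.

    For each AP station and ramp step, the ventral apex of the cross section
    is compared with the reference state's apex at the same station; positive
    values point inward (toward the embryo interior).
    """
    mesh = trajectory.mesh
    ap_stations = np.atleast_1d(np.asarray(ap_stations, dtype=float))
    xmax = mesh.vertices[:, 0].max()
    if np.any(np.abs(ap_stations) >= xmax):
        raise ValueError("stations must lie strictly within the AP extent")
    z_ref = {}
    for x_s in ap_stations:
        sec = extract_section(mesh.vertices, mesh.faces, "cross", x_s)
        z_ref[x_s] = _ventral_apex(sec)[1]
    rows = []
    for k, st in enumerate(trajectory.states):
        for x_s in ap_stations:
            sec = extract_section(st.positions, mesh.faces, "cross", x_s)
            depth = _ventral_apex(sec)[1] - z_ref[x_s]
            rows.append(
                dict(step=k, eps_midline=st.eps_midline, station=x_s, depth=depth)
            )
    return pd.DataFrame(rows)


def distance_map_to_vitelline(state, vitelline: VitellineSurface) -> np.ndarray:
    """Per-vertex apical-to-vitelline distance (non-negative)."""
    pos = state.positions if isinstance(state, SolverState) else np.asarray(state)
    return np.maximum(vitelline.signed_distance(pos), 0.0)


def pole_displacement(
    trajectory: Trajectory, vitelline: VitellineSurface, pole: str = "anterior"
) -> np.ndarray:
    """Distance between the (fixed) vitelline pole and the pole-most surface point.

    At the reference state this equals the perivitelline gap; it grows as the
    contracting ventral tissue pulls the polar caps inward.
    """
    mesh = trajectory.mesh
    sgn = 1.0 if pole == "anterior" else -1.0
    a = mesh.shape.ap_semi_axis
    pole_pt = np.array([sgn * (a + vitelline.gap), 0.0, 0.0])
    # the pole-most cell is a material point: track the reference pole vertex
    i = int(np.argmax(sgn * mesh.vertices[:, 0]))
    return np.asarray(
        [float(np.linalg.norm(st.positions[i] - pole_pt)) for st in trajectory.states]
    )


def _marker_anchor(mesh: EmbryoMesh, point3d: np.ndarray):
    """(face index, barycentric coords) of the reference point on the mesh.

    Candidate facets are ranked by centroid distance; the closest point on
    each candidate triangle is found by barycentric projection with edge
    clamping.
    """
    cents = mesh.facet_centroids()
    cand = np.argsort(np.linalg.norm(cents - point3d, axis=1))[:24]
    best = None
    for f in cand:
        a, b, c = mesh.vertices[mesh.faces[f]]
        ab, ac, ap = b - a, c - a, point3d - a
        m = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
        rhs = np.array([ab @ ap, ac @ ap])
        u, v = np.linalg.solve(m, rhs)
        # clamp into the triangle
        if u < 0:
            u = 0.0
            v = np.clip((ac @ ap) / (ac @ ac), 0.0, 1.0)
        elif v < 0:
            v = 0.0
            u = np.clip((ab @ ap) / (ab @ ab), 0.0, 1.0)
        elif u + v > 1:
            s = u + v
            u, v = u / s, v / s
        closest = a + u * ab + v * ac
        d = np.linalg.norm(point3d - closest)
        if best is None or d < best[0]:
            best = (d, int(f), np.array([1.0 - u - v, u, v]))
    return best[1], best[2]


def tissue_shortening(
    trajectory: Trajectory,
    axis: str = "AP",
    marker_offset: float = 1.1,
    station: float = 0.0,
) -> np.ndarray:
    """Surface arc distance between two material markers per ramp step.

    Markers are placed on the reference ventral contour at +/-``marker_offset``
    arc distance from the midline point of the chosen section (mid-sagittal
    for AP, cross section at ``station`` for DV), then tracked as material
    points and their distance measured along the deformed section contour.
    """
    mesh = trajectory.mesh
    plane = "sagittal" if axis == "AP" else "cross"
    sec0 = extract_section(mesh.vertices, mesh.faces, plane, station)
    s0 = sec0.arclength()
    if marker_offset >= 0.5 * (s0[-1]):
        raise ValueError("marker offset exceeds the section half-arc-length")
    apex = _ventral_apex(sec0)
    i0 = int(np.argmin(np.linalg.norm(sec0.points - apex, axis=1)))
    total = s0[-1] + np.linalg.norm(sec0.points[-1] - sec0.points[0])

    anchors = []
    for ds in (-marker_offset, marker_offset):
        target = (s0[i0] + ds) % total
        p3 = np.array(
            [np.interp(target, s0, sec0.points3d[:, k]) for k in range(3)]
        )
        anchors.append(_marker_anchor(mesh, p3))

    out = []
    for st in trajectory.states:
        sec = extract_section(st.positions, mesh.faces, plane, station)
        s = sec.arclength()
        proj = []
        for face, bary in anchors:
            world = bary @ st.positions[mesh.faces[face]]
            # continuous projection onto the section polyline
            a = sec.points3d
            b = np.roll(sec.points3d, -1, axis=0)
            ab = b - a
            denom = np.einsum("ij,ij->i", ab, ab)
            t = np.clip(np.einsum("ij,ij->i", world - a, ab) / denom, 0.0, 1.0)
            close = a + t[:, None] * ab
            j = int(np.argmin(np.linalg.norm(close - world, axis=1)))
            seg_len = np.linalg.norm(ab[j])
            base = s[j] if j < len(s) else s[-1]
            proj.append(base + t[j] * seg_len)
        d = abs(proj[1] - proj[0])
        stot = s[-1] + np.linalg.norm(sec.points[-1] - sec.points[0])
        out.append(min(d, stot - d))
    return np.asarray(out)


# --------------------------------------------------------------------------- #
# local regression (LOESS-style) smoothing and recoil velocity
# --------------------------------------------------------------------------- #
def loess_fit(t, y, frac: float = 0.3, degree: int = 2):
    """Tricube-weighted local polynomial fit.

    Returns (fitted values, first derivatives) evaluated at each sample; the
    derivative comes from the local polynomial's slope, following the moving-
    window local-regression approach used for tracking-derived time series.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    if n < degree + 2:
        raise ValueError("not enough samples for the local fit")
    half = max(0.5 * frac * (t[-1] - t[0]), 1e-12)
    fitted = np.empty(n)
    slope = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        w = np.clip(1.0 - (d / half) ** 3, 0.0, None) ** 3
        use = w > 0
        if use.sum() < degree + 1:
            order = np.argsort(d)[: degree + 2]
            use = np.zeros(n, dtype=bool)
            use[order] = True
            w[use] = 1.0
        dt = t[use] - t[i]
        vand = np.vander(dt, degree + 1, increasing=True)
        wm = w[use]
        a, *_ = np.linalg.lstsq(vand * wm[:, None], y[use] * wm, rcond=None)
        fitted[i] = a[0]
        slope[i] = a[1]
    return fitted, slope


def recoil_velocity(trace, frac: float = 0.3, degree: int = 2) -> float:
    """Maximum recoil velocity: peak of the smoothed first derivative.

    ``trace`` is a DataFrame with (time, displacement) columns or a pair of
    arrays.  Requires at least 3 samples with strictly increasing times.
    """
    if isinstance(trace, pd.DataFrame):
        t, y = trace["time"].to_numpy(), trace["displacement"].to_numpy()
    else:
        t, y = (np.asarray(a, dtype=float) for a in trace)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    _, slope = loess_fit(t, y, frac=frac, degree=min(degree, len(t) - 2))
    return float(slope.max())
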