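"""Embryo surface geometry: reference mesh, mesoderm labelling, pre-strain, vitelline.

The reference configuration is a closed triangulated ovoid whose long (AP)
axis is ``ap_dv_ratio`` times the short (DV) axis, with the ventral side more
curved than the dorsal one and exact mirror symmetry about the mid-sagittal
(y = 0) and mid-transverse (x = 0) planes.  Lengths are nondimensionalised by
the DV semi-axis; the coordinate convention is x = AP, z = DV with the
ventral side at z < 0.

Actomyosin contractility is encoded as an areal pre-strain field: mesoderm
facets are given a target area A_0 smaller than their reference area A_i so
that each facet carries pre-strain eps_a = (A_i - A_0)/A_0 and pre-stress
sigma_a = chi_2d * eps_a before any deformation occurs.  The field is graded
with DV distance from the ventral midline, measured in cell-row units, and
vanishes beyond roughly seven rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import trimesh

from ._ovoid import OvoidShape

__all__ = [
    "GeometryParams",
    "MesodermExtent",
    "GaussianRowProfile",
    "TabulatedRowProfile",
    "EmbryoMesh",
    "VitellineSurface",
    "generate_embryo_mesh",
    "build_vitelline",
    "assign_prestrain",
]


# --------------------------------------------------------------------------- #
# parameters
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class MesodermExtent:
    """Arc-fraction extents of the pre-strained (prospective mesoderm) region.

    ``dv_arc_fraction`` is the fraction of each cross-section contour the
    region spans (centred on the ventral midline); ``ap_arc_fraction`` is the
    fraction of the mid-sagittal contour it spans along AP.  The defaults make
    the region about three times shorter than the mid-sagittal contour and six
    times shorter than the mid-cross contour.
    """

    dv_arc_fraction: float = 1.0 / 6.0
    ap_arc_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.dv_arc_fraction < 1:
            raise ValueError("dv_arc_fraction must lie in (0, 1)")
        if not 0 < self.ap_arc_fraction < 1:
            raise ValueError("ap_arc_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the reference embryo surface.

    ap_dv_ratio : AP extent over DV extent (dimensionless, > 1).
    dissymmetry : ventral-vs-dorsal curvature bias (>= 0; 0 restores mirror
        symmetry about the mid-coronal plane).
    subdivisions : octahedral sphere subdivision level; the mesh has
        8 * 4**subdivisions facets.
    mesoderm_extent : arc extents of the pre-strained region.
    n_dv_cells : nominal number of cells around a mid-cross contour; one
        cell-row unit of DV distance is (mid-cross circumference)/n_dv_cells.
    """

    ap_dv_ratio: float = 3.0
    dissymmetry: float = 0.15
    subdivisions: int = 5
    mesoderm_extent: MesodermExtent = field(default_factory=MesodermExtent)
    n_dv_cells: int = 80

    def __post_init__(self) -> None:
        if not self.ap_dv_ratio > 1:
            raise ValueError("ap_dv_ratio must exceed 1")
        if self.dissymmetry < 0:
            raise ValueError("dissymmetry must be non-negative")
        if self.subdivisions < 1:
            raise ValueError("subdivisions must be >= 1")
        if self.n_dv_cells < 4:
            raise ValueError("n_dv_cells must be >= 4")

    @property
    def shape(self) -> OvoidShape:
        return OvoidShape(self.ap_dv_ratio, self.dissymmetry)


# --------------------------------------------------------------------------- #
# row profiles
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class GaussianRowProfile:
    """Monotone pre-strain / MyoII row profile ``exp(-(row/r0)**p)``.

    Normalised to 1 at the midline; with the defaults it drops below 0.05 by
    row 7, matching the observed graded MyoII support of about seven rows.
    """

    r0: float = 4.0
    p: float = 2.0

    def __call__(self, row: np.ndarray) -> np.ndarray:
        row = np.asarray(row, dtype=float)
        return np.exp(-np.abs(row / self.r0) ** self.p)


@dataclass(frozen=True)
class TabulatedRowProfile:
    """Row profile interpolated from a user-supplied lookup table."""

    rows: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.values) or len(self.rows) < 2:
            raise ValueError("need matching rows/values with at least 2 entries")
        if not np.isclose(self.values[0], 1.0):
            raise ValueError("profile must be normalised to 1 at row 0")

    def __call__(self, row: np.ndarray) -> np.ndarray:
        return np.interp(np.abs(row), self.rows, self.values, right=0.0)


# --------------------------------------------------------------------------- #
# embryo mesh
# --------------------------------------------------------------------------- #
MESODERM = 1
OTHER = 0


@dataclass
class EmbryoMesh:
    """Closed triangulated embryo surface with per-facet mechanical fields."""

    vertices: np.ndarray  # (V, 3) reference positions
    faces: np.ndarray  # (F, 3) outward-oriented
    reference_area: np.ndarray  # (F,) A_i
    target_area: np.ndarray  # (F,) A_0, <= A_i
    region: np.ndarray  # (F,) MESODERM / OTHER
    row_distance: np.ndarray  # (F,) DV arc-distance in cell-row units
    params: GeometryParams

    @property
    def shape(self) -> OvoidShape:
        return self.params.shape

    @property
    def prestrain(self) -> np.ndarray:
        """Areal pre-strain eps_a = (A_i - A_0)/A_0 per facet."""
        return (self.reference_area - self.target_area) / self.target_area

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self, vertices: np.ndarray | None = None) -> trimesh.Trimesh:
        v = self.vertices if vertices is None else vertices
        return trimesh.Trimesh(vertices=v, faces=self.faces, process=False)

    def facet_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        tri = v[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def facet_centroids(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        return v[self.faces].mean(axis=1)

    def enclosed_volume(self, vertices: np.ndarray | None = None) -> float:
        v = self.vertices if vertices is None else vertices
        tri = v[self.faces]
        return float(np.einsum("ij,ij->", np.cross(tri[:, 0], tri[:, 1]), tri[:, 2]) / 6.0)

    def euler_characteristic(self) -> int:
        n_edges = len(self.to_trimesh().edges_unique)
        return self.n_vertices - n_edges + self.n_faces

    def aspect_quality(self) -> np.ndarray:
        """Per-facet inradius/circumradius quality, 1 for equilateral (scaled)."""
        tri = self.vertices[self.faces]
        a = np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1)
        b = np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1)
        c = np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1)
        s = 0.5 * (a + b + c)
        area = self.facet_areas()
        inradius = area / s
        circum = a * b * c / (4.0 * area)
        return 2.0 * inradius / circum  # == 1 for equilateral


# --------------------------------------------------------------------------- #
# mesh generation
# --------------------------------------------------------------------------- #
def _octasphere(subdivisions: int) -> trimesh.Trimesh:
    """Subdivided octahedron projected to the unit sphere.

    Unlike the icosphere, the vertex set contains the six axis poles exactly
    and is invariant under all three coordinate mirror reflections, which the
    embryo's symmetry planes and the exact AP/DV extents rely on.
    """
    verts = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
            [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
        ]
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    for _ in range(subdivisions):
        mesh = mesh.subdivide()
        v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def generate_embryo_mesh(params: GeometryParams | None = None) -> EmbryoMesh:
    """Generate the closed reference embryo mesh with region and row fields.

    Raises
    ------
    ValueError
        If the subdivision level is too low to resolve the mesoderm region.
    """
    params = params or GeometryParams()
    shape = params.shape
    sphere = _octasphere(params.subdivisions)
    q = sphere.vertices
    vertices = shape.map_sphere(q)
    faces = np.asarray(sphere.faces)

    mesh = EmbryoMesh(
        vertices=vertices,
        faces=faces,
        reference_area=np.zeros(len(faces)),
        target_area=np.zeros(len(faces)),
        region=np.zeros(len(faces), dtype=np.int8),
        row_distance=np.zeros(len(faces)),
        params=params,
    )
    mesh.reference_area = mesh.facet_areas()
    mesh.target_area = mesh.reference_area.copy()

    # facet centroids pulled back to the sphere define (u, phi) coordinates
    cq = shape.inverse_map(mesh.facet_centroids())
    cq /= np.linalg.norm(cq, axis=1, keepdims=True)
    u = np.clip(cq[:, 0], -1.0, 1.0)
    phi = np.arctan2(np.abs(cq[:, 1]), -cq[:, 2])  # 0 = ventral, pi = dorsal

    dv_arc = shape.cross_arclength(u, phi)
    row_unit = float(shape.cross_circumference(0.0)[0]) / params.n_dv_cells
    mesh.row_distance = dv_arc / row_unit

    ext = params.mesoderm_extent
    dv_ok = dv_arc <= 0.5 * ext.dv_arc_fraction * shape.cross_circumference(u)
    sag_perimeter = shape.sagittal_perimeter()
    ap_ok = shape.sagittal_arclength(np.abs(u)) <= 0.5 * ext.ap_arc_fraction * sag_perimeter
    mesh.region = np.where(dv_ok & ap_ok, MESODERM, OTHER).astype(np.int8)

    n_meso = int((mesh.region == MESODERM).sum())
    if n_meso < 24:
        raise ValueError(
            f"subdivision level {params.subdivisions} resolves only {n_meso} "
            "mesoderm facets; increase 'subdivisions' so the pre-strained "
            "region spans at least 24 facets"
        )
    return mesh


# --------------------------------------------------------------------------- #
# pre-strain assignment
# --------------------------------------------------------------------------- #
def assign_prestrain(
    mesh: EmbryoMesh,
    profile: Callable[[np.ndarray], np.ndarray] | None = None,
    eps_midline: float = 0.0,
) -> EmbryoMesh:
    """Return a copy of ``mesh`` with target areas set from the pre-strain field.

    Mesoderm facets receive ``A_0 = A_i / (1 + eps_midline * profile(row))``;
    all other facets keep ``A_0 = A_i``.
    """
    if eps_midline < 0:
        raise ValueError("midline pre-strain must be non-negative")
    profile = profile or GaussianRowProfile()
    eps = np.zeros(mesh.n_faces)
    meso = mesh.region == MESODERM
    eps[meso] = eps_midline * np.asarray(profile(mesh.row_distance[meso]))
    out = replace(mesh)
    out.target_area = mesh.reference_area / (1.0 + eps)
    return out


# --------------------------------------------------------------------------- #
# vitelline surface
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class VitellineSurface:
    """Rigid containment surface: the reference ovoid offset outward by ``gap``.

    Signed distance is positive inside (the feasible region), zero on the
    vitelline, negative outside.  The reference embryo surface sits at signed
    distance ``gap`` by construction.
    """

    shape: OvoidShape
    gap: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return self.gap - self.shape.signed_distance(points)

    def signed_distance_gradient(self, points: np.ndarray):
        d, g = self.shape.signed_distance_gradient(points)
        return self.gap - d, -g

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.signed_distance(points) >= -tol

    def project_inside(self, points: np.ndarray, n_iter: int = 2) -> np.ndarray:
        """Project offending points back onto the vitelline surface."""
        p = np.array(points, dtype=float)
        for _ in range(n_iter):
            sd, grad = self.signed_distance_gradient(p)
            bad = sd < 0.0
            if not bad.any():
                break
            g = grad[bad]
            p[bad] += (-sd[bad] / np.einsum("ij,ij->i", g, g))[:, None] * g
        return p

    def perivitelline_volume(self, mesh: EmbryoMesh) -> float:
        """Initial fluid volume between the embryo surface and the vitelline."""
        normals = self.shape.surface_normal(mesh.vertices)
        offset = mesh.vertices + self.gap * normals
        return mesh.enclosed_volume(offset) - mesh.enclosed_volume()


def build_vitelline(mesh: EmbryoMesh, gap: float) -> VitellineSurface:
    """Build the rigid vitelline envelope at apical-to-vitelline distance ``gap``.

    The physical perivitelline gap is ~0.2-0.5 um; with a DV semi-axis of
    ~90 um that is ~0.002-0.006 in code units.
    """
    if gap <= 0:
        raise ValueError("gap must be strictly positive")
    if gap >= 0.2:
        raise ValueError(
            "gap is a large fraction of the DV semi-axis; the offset "
            "construction (and the thin perivitelline layer it models) "
            "requires gap << 1"
        )
    vit = VitellineSurface(shape=mesh.shape, gap=gap)
    if not vit.contains(mesh.vertices, tol=-0.5 * gap).all():
        raise ValueError("mesh vertices are not strictly inside the vitelline")
    return vit
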