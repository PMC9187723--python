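"""Per-facet stress tensors, principal stresses and angular profiles.

The membrane stress of a converged state is evaluated against each facet's
target metric (the derivative of the stretching energy density with respect
to the Green strain, pushed forward to the current configuration as a Cauchy
membrane tension) and expressed in a local tangent frame aligned with the
embryo axes: the AP direction is the global x axis projected onto the facet
plane, the DV direction its in-plane perpendicular.  Facets whose normal is
nearly parallel to the AP axis (the polar caps) have no meaningful AP/DV
split and are excluded from axis-aligned extracts.

Angular profiles bin facet scalars by the DV angle from the ventral midline
(0 at the ventral apex, pi at the dorsal apex), area-weighted within bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EmbryoMesh, MESODERM
from .shell_solver import ElasticParams, ShellModel, SolverState

__all__ = [
    "StressField",
    "AngularProfile",
    "facet_stress",
    "principal_stress_map",
    "anisotropy_ratio",
    "strain_profile",
    "dv_angle",
]


def dv_angle(mesh: EmbryoMesh) -> np.ndarray:
    """DV angle of each facet centroid: 0 ventral midline, pi dorsal midline."""
    cq = mesh.shape.inverse_map(mesh.facet_centroids())
    cq = cq / np.linalg.norm(cq, axis=1, keepdims=True)
    return np.arctan2(np.abs(cq[:, 1]), -cq[:, 2])


@dataclass
class StressField:
    """In-plane Cauchy membrane stress per facet in the (AP, DV) tangent frame."""

    tensor: np.ndarray  # (F, 2, 2) symmetric, [0,0]=AP-AP, [1,1]=DV-DV
    frame_ap: np.ndarray  # (F, 3) unit AP tangent direction
    frame_dv: np.ndarray  # (F, 3) unit DV tangent direction
    polar_mask: np.ndarray  # (F,) True where the AP/DV frame is degenerate
    converged: bool

    @property
    def sigma_ap(self) -> np.ndarray:
        return self.tensor[:, 0, 0]

    @property
    def sigma_dv(self) -> np.ndarray:
        return self.tensor[:, 1, 1]

    @property
    def trace(self) -> np.ndarray:
        return self.tensor[:, 0, 0] + self.tensor[:, 1, 1]


@dataclass
class AngularProfile:
    """Binned mean of a facet scalar against the DV angle."""

    angle: np.ndarray  # bin centres (rad)
    value: np.ndarray
    count: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(angle=self.angle, value=self.value, n=self.count))


def facet_stress(
    state,
    mesh: EmbryoMesh,
    params: ElasticParams,
    model: ShellModel | None = None,
) -> StressField:
    """Cauchy membrane stress tensor per facet in the AP/DV tangent frame.

    An unconverged state is accepted (the field is still well defined) but
    the returned ``converged`` flag is False so downstream summaries can warn.
    """
    positions = state.positions if isinstance(state, SolverState) else np.asarray(state)
    converged = state.converged if isinstance(state, SolverState) else True
    model = model or ShellModel(mesh, params, volume_constraint=False)

    _, second_pk, fgrad = model.membrane_stress(positions)
    areas = mesh.facet_areas(positions)
    if np.any(areas <= 0):
        raise ValueError(f"degenerate current facet {int(np.argmin(areas))}")
    jac = areas / mesh.target_area
    # push-forward: sigma = F S F^T / J  (3x3, rank 2 in the tangent plane)
    sigma3 = np.einsum("fki,fij,flj->fkl", fgrad, second_pk, fgrad) / jac[:, None, None]

    tri = positions[mesh.faces]
    normal = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    xhat = np.array([1.0, 0.0, 0.0])
    ap = xhat - normal * normal[:, 0:1]
    ap_norm = np.linalg.norm(ap, axis=1)
    polar = ap_norm < 1e-3
    ap_norm = np.where(polar, 1.0, ap_norm)
    ap = ap / ap_norm[:, None]
    dv = np.cross(normal, ap)

    tensor = np.empty((mesh.n_faces, 2, 2))
    tensor[:, 0, 0] = np.einsum("fi,fij,fj->f", ap, sigma3, ap)
    tensor[:, 1, 1] = np.einsum("fi,fij,fj->f", dv, sigma3, dv)
    tensor[:, 0, 1] = tensor[:, 1, 0] = np.einsum("fi,fij,fj->f", ap, sigma3, dv)
    return StressField(
        tensor=tensor, frame_ap=ap, frame_dv=dv, polar_mask=polar, converged=converged
    )


def principal_stress_map(field: StressField):
    """Eigen-decomposition of the per-facet stress: (sigma1 >= sigma2, dirs).

    Directions are unit 3D tangent vectors; principal values are invariant
    under rotations of the in-plane frame.
    """
    t = field.tensor
    tr = t[:, 0, 0] + t[:, 1, 1]
    det = t[:, 0, 0] * t[:, 1, 1] - t[:, 0, 1] ** 2
    disc = np.sqrt(np.maximum(0.25 * tr**2 - det, 0.0))
    s1 = 0.5 * tr + disc
    s2 = 0.5 * tr - disc
    # eigenvector of the larger eigenvalue in the 2D frame
    a, b, c = t[:, 0, 0], t[:, 0, 1], t[:, 1, 1]
    v = np.where(
        (np.abs(b) > 1e-14)[:, None],
        np.stack([b, s1 - a], axis=1),
        np.where((a >= c)[:, None], np.tile([1.0, 0.0], (len(t), 1)), np.tile([0.0, 1.0], (len(t), 1))),
    )
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    d1 = v[:, 0:1] * field.frame_ap + v[:, 1:2] * field.frame_dv
    d2 = -v[:, 1:2] * field.frame_ap + v[:, 0:1] * field.frame_dv
    return s1, s2, d1, d2


def anisotropy_ratio(
    field: StressField,
    mesh: EmbryoMesh,
    angle_halfwidth: float = np.pi / 16,
    ap_fraction: float = 0.5,
) -> float:
    """Mean AP over mean DV stress in a band around the ventral midline.

    The band spans DV angles within ``angle_halfwidth`` of the ventral apex
    and the central ``ap_fraction`` of the AP extent; means are area-weighted.
    """
    ang = dv_angle(mesh)
    cx = mesh.facet_centroids()[:, 0]
    xmax = mesh.vertices[:, 0].max()
    band = (
        (ang <= angle_halfwidth)
        & (np.abs(cx) <= ap_fraction * xmax)
        & ~field.polar_mask
    )
    if not band.any():
        raise ValueError("midline band contains no facets; widen the band")
    w = mesh.reference_area[band]
    mean_ap = float(np.dot(field.sigma_ap[band], w) / w.sum())
    mean_dv = float(np.dot(field.sigma_dv[band], w) / w.sum())
    floor = 1e-9 * max(abs(mean_ap), 1.0)
    return mean_ap / max(mean_dv, floor)


def strain_profile(
    state,
    mesh: EmbryoMesh,
    params: ElasticParams,
    axis: str = "DV",
    n_bins: int = 64,
    ap_fraction: float = 0.5,
) -> AngularProfile:
    """Angular profile of the current/initial length ratio along AP or DV.

    Stretch is measured against the *reference* (initial) metric, not the
    target, so a value below 1 means the tissue has contracted relative to
    its pre-gastrulation size.  Empty bins are merged into their neighbours.
    """
    if axis not in ("AP", "DV"):
        raise ValueError("axis must be 'AP' or 'DV'")
    positions = state.positions if isinstance(state, SolverState) else np.asarray(state)

    # deformation gradient against the reference metric
    from dataclasses import replace

    ref_mesh = replace(mesh)
    ref_mesh.target_area = mesh.reference_area.copy()
    model = ShellModel(ref_mesh, params, volume_constraint=False)
    _, _, fgrad = model.membrane_stress(positions)

    # reference AP direction expressed in each facet's 2D frame
    t1, t2 = model._frame_ap, model._frame_t2
    nr = np.cross(t1, t2)
    ap3 = np.array([1.0, 0.0, 0.0]) - nr * nr[:, 0:1]
    ap_norm = np.linalg.norm(ap3, axis=1)
    polar = ap_norm < 1e-3
    ap3 = ap3 / np.where(polar, 1.0, ap_norm)[:, None]
    ap2 = np.stack(
        [np.einsum("ij,ij->i", ap3, t1), np.einsum("ij,ij->i", ap3, t2)], axis=1
    )
    dv2 = np.stack([-ap2[:, 1], ap2[:, 0]], axis=1)
    direction = ap2 if axis == "AP" else dv2
    stretch = np.linalg.norm(np.einsum("fki,fi->fk", fgrad, direction), axis=1)

    ang = dv_angle(mesh)
    cx = mesh.facet_centroids()[:, 0]
    xmax = mesh.vertices[:, 0].max()
    keep = (~polar) & (np.abs(cx) <= ap_fraction * xmax)

    edges = np.linspace(0.0, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(ang[keep], edges) - 1, 0, n_bins - 1)
    w = mesh.reference_area[keep]
    val = np.zeros(n_bins)
    wsum = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=int)
    np.add.at(val, idx, stretch[keep] * w)
    np.add.at(wsum, idx, w)
    np.add.at(cnt, idx, 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    # merge empty bins into the nearest populated neighbour
    good = cnt > 0
    val[good] = val[good] / wsum[good]
    if not good.all():
        val[~good] = np.interp(centres[~good], centres[good], val[good])
        cnt[~good] = 0
    return AngularProfile(angle=centres, value=val, count=cnt)
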