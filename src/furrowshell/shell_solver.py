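"""Quasi-static minimisation of the pre-strained elastic shell energy.

The apical surface is a thin elastic shell discretised on the embryo mesh:

* Membrane: constant-strain triangles with Green-Lagrange strain measured
  against each facet's *target* metric (the reference triangle isotropically
  shrunk so its area is A_0).  The energy density per unit target area is

      W = (chi/2) (tr E)^2 + mu_s dev(E):dev(E),

  with chi the in-plane (areal) compression modulus and
  mu_s = chi (1 - nu)/(1 + nu) the in-plane shear modulus, so that a pure
  areal strain eps relative to the target returns an isotropic stress
  chi * eps (exactly: for an isotropic stretch tr E equals the areal strain),
  and nu couples the two strain invariants in the standard plane-stress way.

* Bending: discrete-shells hinge energy on every interior edge,
  (B/2) * 3 |e|^2 / (A1 + A2) * (theta - theta_ref)^2, with the reference
  dihedral subtracted so the undeformed embryo shape is bending-neutral.

* Constraints: the enclosed volume is held at its reference value with an
  augmented Lagrangian (plus an exact final projection along the volume
  gradient), and vertices are confined inside the rigid vitelline surface by
  a frictionless one-sided quadratic penalty followed by projection onto the
  vitelline interior.

Minimisation is deterministic (L-BFGS inner solves, no randomised steps);
buckling direction is selected by the geometry, not injected noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.optimize

from .geometry import EmbryoMesh, GaussianRowProfile, VitellineSurface, MESODERM

__all__ = [
    "ElasticParams",
    "SolverState",
    "RampSchedule",
    "Trajectory",
    "ShellModel",
    "stretch_energy",
    "bend_energy",
    "minimize_energy",
    "ramp_prestrain",
]


# --------------------------------------------------------------------------- #
# parameters and state containers
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class ElasticParams:
    """Elastic moduli of the shell.

    chi_tilde : nondimensional in-plane compression modulus,
        chi_tilde = chi_2d * L^2 / B with L the DV semi-axis (the code length
        unit, so L = 1) and B the bending modulus.
    nu : in-plane Poisson ratio (-1 < nu < 1).
    bending_modulus : B, sets the energy unit (default 1 in code units).
    """

    chi_tilde: float = 50.0
    nu: float = 0.0
    bending_modulus: float = 1.0

    def __post_init__(self) -> None:
        if not self.chi_tilde > 0:
            raise ValueError("chi_tilde must be positive")
        if not -1 < self.nu < 1:
            raise ValueError("nu must lie in (-1, 1)")
        if not self.bending_modulus > 0:
            raise ValueError("bending modulus must be positive")

    @property
    def chi(self) -> float:
        """Dimensional in-plane compression modulus in code units (L = 1)."""
        return self.chi_tilde * self.bending_modulus

    @property
    def shear_modulus(self) -> float:
        return self.chi * (1.0 - self.nu) / (1.0 + self.nu)


@dataclass
class SolverState:
    """Converged (or best-effort) configuration at one ramp step."""

    positions: np.ndarray  # (V, 3)
    eps_midline: float
    energies: dict  # stretch, bend, contact_penalty, volume_multiplier
    volume: float
    grad_norm: float
    n_iter: int
    converged: bool
    energy_trace: np.ndarray | None = None


@dataclass(frozen=True)
class RampSchedule:
    """Ordered, non-decreasing midline pre-strain values for the loading ramp."""

    eps_values: tuple
    tolerance: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.eps_values, dtype=float)
        if vals.ndim != 1 or len(vals) == 0:
            raise ValueError("schedule must be a non-empty 1D sequence")
        if np.any(np.diff(vals) < 0):
            raise ValueError("pre-strain ramp must be non-decreasing")
        if vals[0] < 0:
            raise ValueError("pre-strain must be non-negative")

    def __len__(self) -> int:
        return len(self.eps_values)


@dataclass
class Trajectory:
    """Sequence of solver states along a pre-strain ramp."""

    mesh: EmbryoMesh
    schedule: RampSchedule
    states: list
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.states)

    def manifest(self):
        import pandas as pd

        rows = []
        for k, st in enumerate(self.states):
            rows.append(
                dict(
                    step=k,
                    eps_midline=st.eps_midline,
                    stretch_energy=st.energies["stretch"],
                    bend_energy=st.energies["bend"],
                    contact_penalty=st.energies["contact_penalty"],
                    volume=st.volume,
                    grad_norm=st.grad_norm,
                    n_iter=st.n_iter,
                    converged=st.converged,
                )
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# discrete shell model
# --------------------------------------------------------------------------- #
class ShellModel:
    """Precomputed discrete operators for one (mesh, elastic parameters) pair."""

    def __init__(
        self,
        mesh: EmbryoMesh,
        params: ElasticParams,
        vitelline: VitellineSurface | None = None,
        fixed_mask: np.ndarray | None = None,
        volume_constraint: bool = True,
    ):
        self.mesh = mesh
        self.params = params
        self.vitelline = vitelline
        self.volume_constraint = volume_constraint

        v, f = mesh.vertices, mesh.faces
        self.n_vertices = len(v)
        self.faces = f

        # ---- membrane reference frames -----------------------------------
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        n = np.cross(e1, e2)
        self._ref_area = 0.5 * np.linalg.norm(n, axis=1)
        if np.any(self._ref_area <= 0):
            bad = int(np.argmin(self._ref_area))
            raise ValueError(f"degenerate reference facet {bad}")
        t1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        nn = n / np.linalg.norm(n, axis=1, keepdims=True)
        t2 = np.cross(nn, t1)
        # 2x2 reference edge matrix in the (t1, t2) frame and its inverse
        dm = np.zeros((len(f), 2, 2))
        dm[:, 0, 0] = np.einsum("ij,ij->i", e1, t1)
        dm[:, 0, 1] = np.einsum("ij,ij->i", e2, t1)
        dm[:, 1, 1] = np.einsum("ij,ij->i", e2, t2)
        self._bm_ref = np.linalg.inv(dm)
        self._frame_ap = t1  # kept for stress extraction helpers
        self._frame_t2 = t2

        self.set_target_areas(mesh.target_area)

        # ---- bending stencils --------------------------------------------
        tm = mesh.to_trimesh()
        adj = tm.face_adjacency
        edges = tm.face_adjacency_edges
        opp = tm.face_adjacency_unshared
        # hinges exist on interior (2-face) edges; boundary edges carry no
        # bending, edges shared by 3+ faces are non-manifold and rejected
        edge_mult = np.bincount(tm.edges_unique_inverse)
        if edge_mult.max(initial=0) > 2:
            raise ValueError(
                f"non-manifold edge {int(np.argmax(edge_mult))}: shared by "
                f"{int(edge_mult.max())} faces"
            )
        self._hinge = np.column_stack([edges[:, 0], edges[:, 1], opp[:, 0], opp[:, 1]])
        elen2 = np.einsum("ij,ij->i", v[edges[:, 1]] - v[edges[:, 0]], v[edges[:, 1]] - v[edges[:, 0]])
        area_sum = self._ref_area[adj[:, 0]] + self._ref_area[adj[:, 1]]
        self._hinge_stiff = params.bending_modulus * 3.0 * elen2 / area_sum
        self._theta_ref = self._dihedral(v)[0]

        # ---- volume and vertex weights -----------------------------------
        self.volume0 = mesh.enclosed_volume()
        w = np.zeros(self.n_vertices)
        np.add.at(w, f.ravel(), np.repeat(self._ref_area / 3.0, 3))
        self._vertex_area = w
        self.total_area = float(self._ref_area.sum())

        # ---- free degrees of freedom -------------------------------------
        if fixed_mask is None:
            self._free = np.ones(self.n_vertices, dtype=bool)
        else:
            self._free = ~np.asarray(fixed_mask, dtype=bool)
        self._x_fixed = v.copy()

    # -- target update ------------------------------------------------------
    def set_target_areas(self, target_area: np.ndarray) -> None:
        target_area = np.asarray(target_area, dtype=float)
        if np.any(target_area <= 0) or np.any(target_area > self._ref_area * (1 + 1e-12)):
            raise ValueError("target areas must satisfy 0 < A_0 <= A_i")
        self.target_area = target_area
        scale = np.sqrt(target_area / self._ref_area)
        self._bm = self._bm_ref / scale[:, None, None]

    def set_prestrain(self, eps_midline: float, profile=None) -> None:
        from .geometry import assign_prestrain

        m2 = assign_prestrain(self.mesh, profile, eps_midline)
        self.set_target_areas(m2.target_area)

    # -- membrane -----------------------------------------------------------
    def _deformation(self, x: np.ndarray):
        f = self.faces
        d1 = x[f[:, 1]] - x[f[:, 0]]
        d2 = x[f[:, 2]] - x[f[:, 0]]
        # F = D @ Bm, with D the (3, 2) current edge matrix
        fgrad = (
            d1[:, :, None] * self._bm[:, None, 0, :]
            + d2[:, :, None] * self._bm[:, None, 1, :]
        )
        return d1, d2, fgrad

    def membrane_stress(self, x: np.ndarray):
        """Per-facet Green strain and 2nd Piola-Kirchhoff stress vs target."""
        _, _, fgrad = self._deformation(x)
        c = np.einsum("fki,fkj->fij", fgrad, fgrad)
        strain = 0.5 * (c - np.eye(2))
        tr = np.trace(strain, axis1=1, axis2=2)
        dev = strain - 0.5 * tr[:, None, None] * np.eye(2)
        chi, mu = self.params.chi, self.params.shear_modulus
        stress = chi * tr[:, None, None] * np.eye(2) + 2.0 * mu * dev
        return strain, stress, fgrad

    def membrane_energy_grad(self, x: np.ndarray):
        strain, stress, fgrad = self.membrane_stress(x)
        tr = np.trace(strain, axis1=1, axis2=2)
        dev = strain - 0.5 * tr[:, None, None] * np.eye(2)
        chi, mu = self.params.chi, self.params.shear_modulus
        w = 0.5 * chi * tr**2 + mu * np.einsum("fij,fij->f", dev, dev)
        energy = float(np.dot(self.target_area, w))

        # dE/dD = A0 * (F S) Bm^T, distributed to the triangle vertices
        fs = np.einsum("fki,fij->fkj", fgrad, stress)
        g_edges = self.target_area[:, None, None] * np.einsum(
            "fkj,flj->fkl", fs, self._bm
        )  # (F, 3, 2): columns are forces on edge vectors d1, d2
        grad = np.zeros_like(x)
        f = self.faces
        np.add.at(grad, f[:, 1], g_edges[:, :, 0])
        np.add.at(grad, f[:, 2], g_edges[:, :, 1])
        np.add.at(grad, f[:, 0], -g_edges[:, :, 0] - g_edges[:, :, 1])
        return energy, grad

    # -- bending ------------------------------------------------------------
    def _dihedral(self, x: np.ndarray):
        h = self._hinge
        x0, x1, x2, x3 = x[h[:, 0]], x[h[:, 1]], x[h[:, 2]], x[h[:, 3]]
        e = x1 - x0
        n1 = np.cross(e, x2 - x0)
        n2 = np.cross(x3 - x0, e)
        elen = np.linalg.norm(e, axis=1)
        ehat = e / elen[:, None]
        sin_t = np.einsum("ij,ij->i", np.cross(n1, n2), ehat)
        cos_t = np.einsum("ij,ij->i", n1, n2)
        theta = np.arctan2(sin_t, cos_t)
        return theta, (e, elen, ehat, n1, n2, x0, x1, x2, x3)

    def bending_energy_grad(self, x: np.ndarray):
        theta, (e, elen, ehat, n1, n2, x0, x1, x2, x3) = self._dihedral(x)
        dtheta = theta - self._theta_ref
        energy = float(0.5 * np.dot(self._hinge_stiff, dtheta**2))

        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        a1 = n1 / n1sq[:, None]
        a2 = n2 / n2sq[:, None]
        g2 = -elen[:, None] * a1
        g3 = -elen[:, None] * a2
        c01 = np.einsum("ij,ij->i", x2 - x1, ehat)
        c02 = np.einsum("ij,ij->i", x3 - x1, ehat)
        c11 = np.einsum("ij,ij->i", x2 - x0, ehat)
        c12 = np.einsum("ij,ij->i", x3 - x0, ehat)
        g0 = -c01[:, None] * a1 - c02[:, None] * a2
        g1 = c11[:, None] * a1 + c12[:, None] * a2

        coef = (self._hinge_stiff * dtheta)[:, None]
        grad = np.zeros_like(x)
        h = self._hinge
        np.add.at(grad, h[:, 0], coef * g0)
        np.add.at(grad, h[:, 1], coef * g1)
        np.add.at(grad, h[:, 2], coef * g2)
        np.add.at(grad, h[:, 3], coef * g3)
        return energy, grad

    # -- volume ---------------------------------------------------------------
    def volume_grad(self, x: np.ndarray):
        f = self.faces
        v0, v1, v2 = x[f[:, 0]], x[f[:, 1]], x[f[:, 2]]
        vol = float(np.einsum("ij,ij->", np.cross(v0, v1), v2) / 6.0)
        grad = np.zeros_like(x)
        np.add.at(grad, f[:, 0], np.cross(v1, v2) / 6.0)
        np.add.at(grad, f[:, 1], np.cross(v2, v0) / 6.0)
        np.add.at(grad, f[:, 2], np.cross(v0, v1) / 6.0)
        return vol, grad

    # -- contact --------------------------------------------------------------
    def contact_energy_grad(self, x: np.ndarray, stiffness: float):
        if self.vitelline is None:
            return 0.0, np.zeros_like(x), 0.0
        sd, grad_sd = self.vitelline.signed_distance_gradient(x)
        pen = np.minimum(sd, 0.0)
        w = self._vertex_area
        energy = float(0.5 * stiffness * np.dot(w, pen**2))
        grad = (stiffness * w * pen)[:, None] * grad_sd
        return energy, grad, float(-pen.min())

    def max_penetration(self, x: np.ndarray) -> float:
        if self.vitelline is None:
            return 0.0
        return float(max(0.0, -self.vitelline.signed_distance(x).min()))

    # -- assembled objective ----------------------------------------------------
    def constrained_energy_grad(self, x, lam, mu, kc):
        em, gm = self.membrane_energy_grad(x)
        eb, gb = self.bending_energy_grad(x)
        energy = em + eb
        grad = gm + gb
        vol = self.volume0
        if self.volume_constraint:
            vol, gv = self.volume_grad(x)
            dv = vol - self.volume0
            energy += lam * dv + 0.5 * mu * dv * dv
            grad += (lam + mu * dv) * gv
        ec, gc, _ = self.contact_energy_grad(x, kc)
        energy += ec
        grad += gc
        return energy, grad, dict(stretch=em, bend=eb, contact_penalty=ec, volume=vol)

    def equilibrium_residual(self, x, lam, contact_tol: float = 1e-3):
        """First-order (KKT) residual of the constrained equilibrium.

        Elastic forces plus the volume-pressure reaction, with the admissible
        contact reaction removed at vertices on the vitelline: there the wall
        can only push inward, so an outward-pointing normal force component is
        balanced by the constraint rather than being a genuine residual.
        """
        _, grad, parts = self.constrained_energy_grad(x, lam, 0.0, 0.0)
        if self.volume_constraint:
            _, gv = self.volume_grad(x)
            gv[~self._free] = 0.0
            grad = grad - (np.einsum("ij,ij->", grad, gv) / np.einsum("ij,ij->", gv, gv)) * gv
        if self.vitelline is not None:
            sd, grad_sd = self.vitelline.signed_distance_gradient(x)
            nhat = grad_sd / np.linalg.norm(grad_sd, axis=1, keepdims=True)
            active = sd <= contact_tol
            # residual component along the inward normal; a positive value is
            # an admissible reaction magnitude
            fn = np.einsum("ij,ij->i", grad, nhat)
            remove = active & (fn > 0)
            grad = grad - np.where(remove, fn, 0.0)[:, None] * nhat
        grad[~self._free] = 0.0
        return grad, parts

    def project_volume(self, x: np.ndarray, n_iter: int = 3) -> np.ndarray:
        """Newton projection onto the volume constraint along its gradient."""
        x = x.copy()
        for _ in range(n_iter):
            vol, gv = self.volume_grad(x)
            gv[~self._free] = 0.0
            dv = vol - self.volume0
            if abs(dv) < 1e-14 * self.volume0:
                break
            x -= (dv / np.einsum("ij,ij->", gv, gv)) * gv
        return x


# --------------------------------------------------------------------------- #
# public energy wrappers
# --------------------------------------------------------------------------- #
def _positions(state) -> np.ndarray:
    return state.positions if isinstance(state, SolverState) else np.asarray(state)


def stretch_energy(state, mesh: EmbryoMesh, params: ElasticParams) -> float:
    """Membrane (stretching) energy of a configuration against the target metric."""
    x = _positions(state)
    model = ShellModel(mesh, params, volume_constraint=False)
    areas = mesh.facet_areas(x)
    if np.any(areas <= 0):
        raise ValueError(f"degenerate current facet {int(np.argmin(areas))}")
    return model.membrane_energy_grad(x)[0]


def bend_energy(state, mesh: EmbryoMesh, params: ElasticParams) -> float:
    """Hinge bending energy of a configuration relative to the reference shape."""
    x = _positions(state)
    model = ShellModel(mesh, params, volume_constraint=False)
    return model.bending_energy_grad(x)[0]


# --------------------------------------------------------------------------- #
# minimisation
# --------------------------------------------------------------------------- #
def minimize_energy(
    state,
    mesh: EmbryoMesh,
    params: ElasticParams,
    vitelline: VitellineSurface | None = None,
    tolerance: float | None = None,
    model: ShellModel | None = None,
    eps_midline: float = 0.0,
    max_outer: int = 14,
    inner_maxiter: int = 20000,
    volume_tol: float = 1e-6,
    contact_tol: float = 1e-3,
    record_trace: bool = False,
) -> SolverState:
    """Minimise the constrained shell energy from a feasible initial state.

    The volume constraint is enforced with an augmented Lagrangian and a final
    exact projection along the volume gradient; vitelline containment with an
    adaptive frictionless one-sided penalty followed by projection onto the
    vitelline interior.  The reported gradient norm is the residual of the
    penalised equilibrium immediately before the final feasibility projection
    (the projection itself moves contact vertices by at most the penetration
    tolerance).  Deterministic: identical inputs give identical output.
    """
    if model is None:
        model = ShellModel(mesh, params, vitelline)
    x0 = _positions(state).astype(float).copy()
    if tolerance is None:
        tolerance = 1e-8 * params.chi_tilde * model.total_area

    # feasibility of the start
    if model.volume_constraint:
        v_start = model.volume_grad(x0)[0]
        if abs(v_start - model.volume0) > 1e-3 * model.volume0:
            raise ValueError("initial state does not satisfy the volume constraint")
    if vitelline is not None and model.max_penetration(x0) > 10 * contact_tol:
        raise ValueError("initial state penetrates the vitelline surface")

    free = model._free
    n_free = int(free.sum())
    x_full = x0.copy()

    def unpack(z):
        x = x_full.copy()
        x[free] = z.reshape(n_free, 3)
        return x

    lam, mu = 0.0, 10.0 * params.chi / max(model.volume0, 1e-9)
    mu_max = 1e8 * params.chi / max(model.volume0, 1e-9)
    kc = 400.0 * params.chi
    kc_max = 1e7 * params.chi
    trace: list = []
    total_iters = 0
    converged = False
    dv_prev = np.inf
    gnorm = np.inf

    for _ in range(max_outer):

        def fun(z):
            x = unpack(z)
            e, g, _ = model.constrained_energy_grad(x, lam, mu, kc)
            return e, g[free].ravel()

        callback = None
        if record_trace:
            # record the objective at accepted iterates only (line-search
            # trial evaluations are not monotone and are not states)
            callback = lambda zk: trace.append(fun(zk)[0])  # noqa: E731

        res = scipy.optimize.minimize(
            fun,
            x_full[free].ravel(),
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options=dict(
                maxiter=inner_maxiter,
                maxcor=20,
                ftol=1e-18,
                gtol=max(tolerance / (10.0 * np.sqrt(3.0 * n_free)), 1e-14),
            ),
        )
        x_full = unpack(res.x)
        total_iters += int(res.nit)
        # residual of the penalised equilibrium (volume direction projected out)
        grad = res.jac.reshape(n_free, 3)
        if model.volume_constraint:
            _, gv = model.volume_grad(x_full)
            gvf = gv[free]
            grad = grad - (
                np.einsum("ij,ij->", grad, gvf) / np.einsum("ij,ij->", gvf, gvf)
            ) * gvf
        gnorm = float(np.linalg.norm(grad))

        if model.volume_constraint:
            vol = model.volume_grad(x_full)[0]
            dv_rel = abs(vol - model.volume0) / model.volume0
        else:
            vol, dv_rel = model.volume0, 0.0
        pen = model.max_penetration(x_full)
        if model.volume_constraint:
            lam += mu * (vol - model.volume0)

        if gnorm <= tolerance and dv_rel <= volume_tol and pen <= contact_tol:
            converged = True
            break
        # raise penalty weights only while the violation is not shrinking on
        # its own (multiplier updates do most of the volume work); unbounded
        # growth would wreck the conditioning of the inner solves
        if model.volume_constraint and dv_rel > volume_tol and dv_rel > 0.25 * dv_prev:
            mu = min(mu * 8.0, mu_max)
        dv_prev = dv_rel
        if pen > 0.3 * contact_tol:
            kc = min(kc * 8.0, kc_max)

    # exact feasibility restoration
    if vitelline is not None:
        for _ in range(3):
            x_full[free] = vitelline.project_inside(x_full[free])
            if model.volume_constraint:
                x_full = model.project_volume(x_full)
    elif model.volume_constraint:
        x_full = model.project_volume(x_full)

    _, parts = model.equilibrium_residual(x_full, lam, contact_tol)
    vol = parts["volume"]
    parts = dict(parts)
    parts["volume_multiplier"] = lam
    del parts["volume"]

    return SolverState(
        positions=x_full,
        eps_midline=eps_midline,
        energies=parts,
        volume=vol,
        grad_norm=gnorm,
        n_iter=total_iters,
        converged=converged,
        energy_trace=np.asarray(trace) if record_trace else None,
    )


def ramp_prestrain(
    mesh: EmbryoMesh,
    params: ElasticParams,
    vitelline: VitellineSurface | None,
    schedule: RampSchedule,
    profile=None,
    tolerance: float | None = None,
    **solver_kwargs,
) -> Trajectory:
    """Solve a sequence of equilibria along a non-decreasing pre-strain ramp.

    Each step is warm-started from the previous converged state.  If a step
    fails to converge the trajectory is truncated there and flagged.
    """
    profile = profile or GaussianRowProfile()
    model = ShellModel(mesh, params, vitelline)
    states: list[SolverState] = []
    x = mesh.vertices.copy()
    truncated = False
    for eps in schedule.eps_values:
        model.set_prestrain(float(eps), profile)
        st = minimize_energy(
            x,
            mesh,
            params,
            vitelline,
            tolerance=tolerance if tolerance is not None else schedule.tolerance,
            model=model,
            eps_midline=float(eps),
            **solver_kwargs,
        )
        states.append(st)
        if not st.converged:
            truncated = True
            break
        x = st.positions
    return Trajectory(mesh=mesh, schedule=schedule, states=states, truncated=truncated)
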