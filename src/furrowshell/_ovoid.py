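"""Closed-form ovoid surface used for the embryo and the vitelline envelope.

The surface is the image of the unit sphere under the smooth map

    Phi(q) = (a * q_x,  q_y,  g(q_z)),    g(t) = t - d * t**2,

with ``a`` the AP semi-axis (in units of the DV semi-axis) and ``d`` a
dissymmetry parameter.  ``g`` stretches the ventral half (q_z < 0) and
compresses the dorsal half, so the ventral apex is more curved than the
dorsal one for d > 0 while the mid-sagittal (y = 0) and mid-transverse
(x = 0) mirror symmetries are preserved.  The total DV extent is
g(1) - g(-1) = 2 for any d, so lengths stay nondimensionalised by the DV
semi-axis.

The map is a diffeomorphism of a neighbourhood of the sphere, which gives a
cheap, smooth, first-order-accurate signed distance to the surface: pull a
query point back with Phi^-1 and rescale the spherical level ``|q| - 1`` by
the local metric distortion.  This is what the rigid-containment constraint
of the solver evaluates, so it must be fast and have an exact gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OvoidShape"]


@dataclass(frozen=True)
class OvoidShape:
    """Analytic embryo surface: sphere mapped by ``(a q_x, q_y, q_z - d q_z^2)``."""

    ap_semi_axis: float = 3.0
    dissymmetry: float = 0.15

    def __post_init__(self) -> None:
        if not self.ap_semi_axis > 0:
            raise ValueError("ap_semi_axis must be positive")
        if not 0 <= self.dissymmetry < 0.5:
            raise ValueError("dissymmetry must lie in [0, 0.5) for an invertible map")

    # -- forward / inverse map ------------------------------------------------
    def map_sphere(self, q: np.ndarray) -> np.ndarray:
        """Map points on (or near) the unit sphere to the ovoid."""
        q = np.asarray(q, dtype=float)
        p = np.empty_like(q)
        p[..., 0] = self.ap_semi_axis * q[..., 0]
        p[..., 1] = q[..., 1]
        p[..., 2] = q[..., 2] - self.dissymmetry * q[..., 2] ** 2
        return p

    def inverse_map(self, p: np.ndarray) -> np.ndarray:
        """Pull ambient points back to sphere coordinates."""
        p = np.asarray(p, dtype=float)
        d = self.dissymmetry
        q = np.empty_like(p)
        q[..., 0] = p[..., 0] / self.ap_semi_axis
        q[..., 1] = p[..., 1]
        if d == 0.0:
            q[..., 2] = p[..., 2]
        else:
            # root of d t^2 - t + z = 0 that tends to z as d -> 0
            q[..., 2] = (1.0 - np.sqrt(1.0 - 4.0 * d * p[..., 2])) / (2.0 * d)
        return q

    # -- signed distance ------------------------------------------------------
    def _metric_terms(self, p: np.ndarray):
        """Common quantities for the approximate SDF and its gradient."""
        q = self.inverse_map(p)
        r = np.linalg.norm(q, axis=-1)
        # gamma = g'(q_z) evaluated on the pulled-back point
        gamma = 1.0 - 2.0 * self.dissymmetry * q[..., 2]
        m = np.empty_like(q)  # m = grad_p |q| * r
        m[..., 0] = q[..., 0] / self.ap_semi_axis
        m[..., 1] = q[..., 1]
        m[..., 2] = q[..., 2] / gamma
        s = np.linalg.norm(m, axis=-1)
        return q, r, gamma, m, s

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the surface (negative inside).

        First-order accurate in the distance; exact on the surface itself.
        """
        _, r, _, _, s = self._metric_terms(p)
        return (r - 1.0) * r / s

    def signed_distance_gradient(self, p: np.ndarray):
        """Signed distance and its exact gradient (of the approximant)."""
        q, r, gamma, m, s = self._metric_terms(p)
        d = (r * r - r) / s

        # grad_p r = m / r  (chain rule through Phi^-1)
        grad_r = m / r[..., None]

        # grad_p (s^2): elementwise through q(p)
        dd = self.dissymmetry
        grad_s2 = np.empty_like(m)
        grad_s2[..., 0] = 2.0 * q[..., 0] / self.ap_semi_axis**3
        grad_s2[..., 1] = 2.0 * q[..., 1]
        grad_s2[..., 2] = (
            2.0 * q[..., 2] / gamma**2 + 4.0 * dd * q[..., 2] ** 2 / gamma**3
        ) / gamma
        grad_s = grad_s2 / (2.0 * s[..., None])

        grad = ((2.0 * r - 1.0) / s)[..., None] * grad_r - (
            (r * r - r) / s**2
        )[..., None] * grad_s
        return d, grad

    def surface_normal(self, p: np.ndarray) -> np.ndarray:
        """Outward unit normal of the level set through ``p``."""
        _, grad = self.signed_distance_gradient(p)
        return grad / np.linalg.norm(grad, axis=-1, keepdims=True)

    # -- contours -------------------------------------------------------------
    def cross_contour(self, u: float, phi: np.ndarray) -> np.ndarray:
        """Points of the cross-section contour at sphere coordinate q_x = u.

        ``phi`` is the angle from the ventral point of the contour
        (phi = 0 -> ventral, phi = pi -> dorsal).
        """
        rad = np.sqrt(max(1.0 - u * u, 0.0))
        q = np.stack(
            [np.full_like(phi, u), rad * np.sin(phi), -rad * np.cos(phi)], axis=-1
        )
        return self.map_sphere(q)

    def cross_arclength(self, u, phi):
        """Arc length along a cross contour from the ventral midline to ``phi``.

        Vectorised over matching arrays ``u`` and ``phi``; uses composite
        Simpson quadrature on a fixed number of samples per contour.
        """
        u = np.atleast_1d(np.asarray(u, dtype=float))
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        n = 129
        t = np.linspace(0.0, 1.0, n)
        ang = phi[:, None] * t[None, :]
        rad = np.sqrt(np.clip(1.0 - u * u, 0.0, None))[:, None]
        qz = -rad * np.cos(ang)
        gamma = 1.0 - 2.0 * self.dissymmetry * qz
        # |dp/dphi| = rad * sqrt(cos^2 + gamma^2 sin^2)
        speed = rad * np.sqrt(np.cos(ang) ** 2 + (gamma * np.sin(ang)) ** 2)
        from scipy.integrate import simpson

        return phi * simpson(speed, x=t, axis=1)

    def cross_circumference(self, u) -> np.ndarray:
        """Total length of the cross contour(s) at sphere coordinate u."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return 2.0 * self.cross_arclength(u, np.full(u.shape, np.pi))

    def sagittal_arclength(self, u) -> np.ndarray:
        """Arc length along the ventral mid-sagittal line from x = 0 to q_x = u."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        psi = np.arcsin(np.clip(u, -1.0, 1.0))
        n = 129
        t = np.linspace(0.0, 1.0, n)
        ang = psi[:, None] * t[None, :]
        qz = -np.cos(ang)
        gamma = 1.0 - 2.0 * self.dissymmetry * qz
        # p(psi) = (a sin psi, 0, g(-cos psi))
        speed = np.sqrt(
            (self.ap_semi_axis * np.cos(ang)) ** 2 + (gamma * np.sin(ang)) ** 2
        )
        from scipy.integrate import simpson

        return np.abs(psi) * simpson(speed, x=t, axis=1)

    def sagittal_perimeter(self) -> float:
        """Full perimeter of the mid-sagittal contour (numerical)."""
        psi = np.linspace(0.0, 2.0 * np.pi, 4097)
        q = np.stack([np.sin(psi), np.zeros_like(psi), -np.cos(psi)], axis=-1)
        p = self.map_sphere(q)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        return float(seg.sum())
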