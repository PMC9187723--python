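"""Stress tensors, principal decomposition, profiles on solved states."""

import numpy as np
import pytest

from furrowshell.geometry import assign_prestrain
from furrowshell.shell_solver import ShellModel
from furrowshell.stress_analysis import (
    StressField,
    anisotropy_ratio,
    dv_angle,
    facet_stress,
    principal_stress_map,
    strain_profile,
)


def synthetic_field(mesh, sigma_ap, sigma_dv, shear=0.0):
    n_f = mesh.n_faces
    tensor = np.zeros((n_f, 2, 2))
    tensor[:, 0, 0] = sigma_ap
    tensor[:, 1, 1] = sigma_dv
    tensor[:, 0, 1] = tensor[:, 1, 0] = shear
    ap = np.tile([1.0, 0.0, 0.0], (n_f, 1))
    dv = np.tile([0.0, 1.0, 0.0], (n_f, 1))
    return StressField(
        tensor=tensor,
        frame_ap=ap,
        frame_dv=dv,
        polar_mask=np.zeros(n_f, dtype=bool),
        converged=True,
    )


class TestFacetStress:
    def test_zero_strain_zero_tensor(self, small_mesh, elastic):
        mesh = assign_prestrain(small_mesh, eps_midline=0.0)
        field = facet_stress(mesh.vertices, mesh, elastic)
        np.testing.assert_allclose(field.tensor, 0.0, atol=1e-10)

    def test_isotropic_prestrain_gives_prestress(self, small_mesh, elastic):
        # held at the reference shape, each pre-strained facet carries the
        # isotropic Cauchy stress chi * eps_a
        mesh = assign_prestrain(small_mesh, eps_midline=0.2)
        field = facet_stress(mesh.vertices, mesh, elastic)
        sa = elastic.chi * mesh.prestrain
        keep = ~field.polar_mask
        np.testing.assert_allclose(field.sigma_ap[keep], sa[keep], rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(field.sigma_dv[keep], sa[keep], rtol=1e-9, atol=1e-9)

    def test_matches_finite_difference_of_energy(self, small_mesh, elastic):
        # global consistency: the membrane gradient (FD-checked elsewhere)
        # is assembled from the same per-facet stress
        mesh = assign_prestrain(small_mesh, eps_midline=0.1)
        rng = np.random.default_rng(2)
        x = mesh.vertices + 1e-3 * rng.standard_normal(mesh.vertices.shape)
        model = ShellModel(mesh, elastic, volume_constraint=False)
        _, grad = model.membrane_energy_grad(x)
        h = 1e-6
        for i in rng.choice(mesh.n_vertices, 3, replace=False):
            for ax in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, ax] += h
                xm[i, ax] -= h
                fd = (
                    model.membrane_energy_grad(xp)[0]
                    - model.membrane_energy_grad(xm)[0]
                ) / (2 * h)
                assert fd == pytest.approx(grad[i, ax], rel=1e-5, abs=1e-8)

    def test_unconverged_state_flagged(self, small_mesh, elastic):
        from furrowshell.shell_solver import SolverState

        mesh = assign_prestrain(small_mesh, eps_midline=0.1)
        st = SolverState(
            positions=mesh.vertices,
            eps_midline=0.1,
            energies={},
            volume=0.0,
            grad_norm=1.0,
            n_iter=0,
            converged=False,
        )
        assert facet_stress(st, mesh, elastic).converged is False


class TestPrincipalStress:
    def test_diagonal_tensor(self, small_mesh):
        field = synthetic_field(small_mesh, 3.0, 1.0)
        s1, s2, d1, d2 = principal_stress_map(field)
        np.testing.assert_allclose(s1, 3.0)
        np.testing.assert_allclose(s2, 1.0)
        np.testing.assert_allclose(np.abs(d1[:, 0]), 1.0)
        np.testing.assert_allclose(np.abs(d2[:, 1]), 1.0)

    def test_rotation_invariance_of_principal_values(self, small_mesh):
        rng = np.random.default_rng(0)
        base = synthetic_field(small_mesh, 2.0, -1.0, shear=0.7)
        s1a, s2a, _, _ = principal_stress_map(base)
        # rotate the in-plane frame by a random angle: tensor components
        # change, eigenvalues must not
        th = rng.uniform(0, np.pi)
        c, s = np.cos(th), np.sin(th)
        r = np.array([[c, -s], [s, c]])
        rotated = synthetic_field(small_mesh, 0, 0)
        rotated.tensor[:] = r.T @ base.tensor[0] @ r
        s1b, s2b, _, _ = principal_stress_map(rotated)
        np.testing.assert_allclose(s1a, s1b, atol=1e-12)
        np.testing.assert_allclose(s2a, s2b, atol=1e-12)

    def test_ordering(self, small_mesh):
        field = synthetic_field(small_mesh, -5.0, 2.0, shear=0.3)
        s1, s2, _, _ = principal_stress_map(field)
        assert (s1 >= s2).all()

    def test_compression_collar_beyond_mesoderm(self, solved_043, elastic):
        # just beyond the pre-strained region's periphery one principal
        # stress is negative (hoop compression from centripetal motion)
        mesh, st = solved_043
        field = facet_stress(st, mesh, elastic)
        s1, s2, _, _ = principal_stress_map(field)
        ang = dv_angle(mesh)
        cx = mesh.facet_centroids()[:, 0]
        collar = (
            (mesh.region == 0)
            & (ang > np.pi / 6)
            & (ang < np.pi / 2.5)
            & (np.abs(cx) < 1.5)
        )
        assert collar.sum() > 10
        assert (s2[collar] < 0).mean() > 0.5
        # while both principal stresses are positive inside the mesoderm core
        core = (mesh.region == 1) & (ang < np.pi / 12) & (np.abs(cx) < 1.5)
        assert (s2[core] > 0).all()


class TestAnisotropyRatio:
    def test_isotropic_field_gives_one(self, small_mesh):
        field = synthetic_field(small_mesh, 2.0, 2.0)
        assert anisotropy_ratio(field, small_mesh) == pytest.approx(1.0)

    def test_pure_ap_field_guarded(self, small_mesh):
        field = synthetic_field(small_mesh, 5.0, 0.0)
        assert anisotropy_ratio(field, small_mesh) > 1e3

    def test_empty_band_rejected(self, small_mesh):
        field = synthetic_field(small_mesh, 1.0, 1.0)
        with pytest.raises(ValueError, match="band"):
            anisotropy_ratio(field, small_mesh, angle_halfwidth=1e-9)

    def test_solved_state_ap_exceeds_dv(self, solved_043, elastic):
        mesh, st = solved_043
        field = facet_stress(st, mesh, elastic)
        assert anisotropy_ratio(field, mesh) > 1.5

    def test_midline_ap_stress_close_to_prestress(self, solved_043, elastic):
        # little deformation happens along AP, so the AP stress stays within
        # ~15% of the imposed pre-stress at the midline
        mesh, st = solved_043
        field = facet_stress(st, mesh, elastic)
        ang = dv_angle(mesh)
        cx = mesh.facet_centroids()[:, 0]
        band = (ang <= np.pi / 16) & (np.abs(cx) <= 1.5)
        sa = elastic.chi * mesh.prestrain
        rel = field.sigma_ap[band] / sa[band]
        assert 0.85 <= np.average(rel, weights=mesh.reference_area[band]) <= 1.15


class TestStrainProfile:
    def test_reference_state_profile_is_unity(self, small_mesh, elastic):
        prof = strain_profile(small_mesh.vertices, small_mesh, elastic, axis="DV")
        good = prof.count > 0
        np.testing.assert_allclose(prof.value[good], 1.0, atol=1e-9)

    def test_ventral_contracts_ventrolateral_stretches(self, solved_043, elastic):
        mesh, st = solved_043
        prof = strain_profile(st, mesh, elastic, axis="DV")
        ventral = prof.angle < np.pi / 8
        vlat = (prof.angle > np.pi / 8) & (prof.angle < np.pi / 4)
        assert prof.value[ventral].mean() < 1.0
        assert prof.value[vlat].mean() > 1.0

    def test_mirrored_state_same_profile(self, solved_043, elastic):
        mesh, st = solved_043
        p1 = strain_profile(st, mesh, elastic, axis="DV")
        mirrored = st.positions.copy()
        mirrored[:, 1] *= -1
        # mirroring about the sagittal plane relabels vertices but leaves the
        # per-facet stretches (and hence the binned profile) unchanged
        from conftest import mirror_map

        partner = mirror_map(mesh.vertices, 1)
        p2 = strain_profile(mirrored[partner], mesh, elastic, axis="DV")
        np.testing.assert_allclose(p1.value, p2.value, atol=1e-6)

    def test_global_force_balance_at_equilibrium(self, solved_043, elastic):
        # total residual force (elastic + pressure + admissible contact
        # reactions) vanishes to solver tolerance at a converged state
        from furrowshell.geometry import build_vitelline
        from conftest import GAP

        mesh, st = solved_043
        vit = build_vitelline(mesh, GAP)
        model = ShellModel(mesh, elastic, vit)
        resid, _ = model.equilibrium_residual(
            st.positions, st.energies["volume_multiplier"]
        )
        scale = elastic.chi * model.total_area
        assert np.linalg.norm(resid) < 5e-3 * scale
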