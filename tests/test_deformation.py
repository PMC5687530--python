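"""Deformation metrics: gradients, Jacobian, ADI, warping, air-volume change,
and the bundled demons field estimator."""

import numpy as np
import pytest
from scipy import ndimage

from qctlung import (
    DisplacementField,
    FractionMap,
    ImageVolume,
    LobeMask,
    RegistrationParams,
    adi,
    adi_from_stretches,
    deformation_gradient,
    estimate_displacement,
    fractional_air_volume_change,
    interior_mask,
    jacobian_determinant,
    lobar_mean,
    principal_stretches,
    warp_scalar,
)

SP = (2.0, 2.0, 2.0)


def world(shape, spacing=SP):
    idx = np.indices(shape, dtype=float)
    return [idx[a] * spacing[a] for a in range(3)]


def affine_field(A, shape, spacing=SP):
    X = world(shape, spacing)
    u = np.zeros(shape + (3,))
    for i in range(3):
        for j in range(3):
            u[..., i] += (A[i, j] - (i == j)) * X[j]
    return DisplacementField(u, spacing)


def sinusoid_field(amp, period, shape, spacing=SP):
    """u_i = amp * sin(2 pi x_i / period): diagonal gradient, analytic J."""
    X = world(shape, spacing)
    u = np.stack([amp * np.sin(2 * np.pi * X[i] / period) for i in range(3)], axis=-1)
    w = 2 * np.pi / period
    J = np.ones(shape)
    for i in range(3):
        J *= 1.0 + amp * w * np.cos(2 * np.pi * X[i] / period)
    return DisplacementField(u, spacing), J


def rotation_field(angle, shape, spacing=SP):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return affine_field(R, shape, spacing)


class TestDeformationGradient:
    def test_zero_field_gives_identity(self):
        F = deformation_gradient(DisplacementField(np.zeros((8, 8, 8, 3)), SP))
        assert F == pytest.approx(np.broadcast_to(np.eye(3), (8, 8, 8, 3, 3)))

    def test_affine_field_exact_interior(self):
        A = np.diag([1.2, 1.1, 0.9])
        F = deformation_gradient(affine_field(A, (16, 16, 16)))
        interior = interior_mask((16, 16, 16))
        assert np.abs(F[interior] - A).max() < 1e-12

    def test_rotation_has_unit_stretches(self):
        F = deformation_gradient(rotation_field(0.3, (12, 12, 12)))
        lam = principal_stretches(F)
        interior = interior_mask((12, 12, 12))
        assert np.abs(lam[interior] - 1.0).max() < 1e-9

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match=">= 3 voxels"):
            deformation_gradient(DisplacementField(np.zeros((2, 8, 8, 3)), SP))


class TestJacobian:
    def test_affine_diagonal_product(self):
        A = np.diag([1.2, 1.1, 0.9])
        F = deformation_gradient(affine_field(A, (16, 16, 16)))
        J = jacobian_determinant(F)
        interior = interior_mask((16, 16, 16))
        assert np.abs(J[interior] - 1.188).max() < 1e-9

    def test_sinusoid_matches_analytic_within_1e3(self):
        field, J_true = sinusoid_field(2.0, 96.0, (32, 32, 32), (1.0, 1.0, 1.0))
        J = jacobian_determinant(deformation_gradient(field))
        interior = interior_mask((32, 32, 32))
        assert np.abs(J - J_true)[interior].max() <= 1e-3

    def test_grid_refinement_second_order_convergence(self):
        errs = []
        for n, h in [(24, 2.0), (48, 1.0), (96, 0.5)]:
            field, J_true = sinusoid_field(2.0, 48.0, (n, n, n), (h, h, h))
            J = jacobian_determinant(deformation_gradient(field))
            interior = interior_mask((n, n, n))
            errs.append(np.abs(J - J_true)[interior].max())
        assert errs[0] > errs[1] > errs[2]
        # roughly fourfold reduction per halving (second-order interior stencil)
        assert errs[1] / errs[0] < 0.35 and errs[2] / errs[1] < 0.35

    def test_det_equals_product_of_stretches(self, rng):
        field, _ = sinusoid_field(1.5, 40.0, (12, 12, 12))
        F = deformation_gradient(field)
        lam = principal_stretches(F)
        assert np.prod(lam, axis=-1) == pytest.approx(jacobian_determinant(F), abs=1e-12)

    def test_folding_warned(self):
        F = np.broadcast_to(np.diag([-1.0, 1.0, 1.0]), (4, 4, 4, 3, 3)).copy()
        with pytest.warns(RuntimeWarning, match="folding"):
            jacobian_determinant(F, np.ones((4, 4, 4), bool))


class TestADI:
    def test_hand_oracle(self):
        # sqrt((0.1/1.1)^2 + (0.2/0.9)^2)
        assert adi_from_stretches(np.array([1.2, 1.1, 0.9])) == pytest.approx(0.240099, abs=1e-5)

    def test_isotropic_and_rigid_are_zero(self):
        assert adi_from_stretches(np.array([1.3, 1.3, 1.3])) <= 1e-12
        F = deformation_gradient(rotation_field(0.5, (12, 12, 12)))
        interior = interior_mask((12, 12, 12))
        assert np.abs(adi(F)[interior]).max() <= 1e-6

    def test_stretch_order_is_irrelevant(self):
        assert adi_from_stretches(np.array([0.9, 1.2, 1.1])) == pytest.approx(
            adi_from_stretches(np.array([1.2, 1.1, 0.9]))
        )

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            adi_from_stretches(np.array([1.0, 1.0, 0.0]))


class TestWarpScalar:
    def test_zero_field_is_identity(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 8, 8)), SP)
        out = warp_scalar(vol, DisplacementField(np.zeros((8, 8, 8, 3)), SP))
        assert out.data == pytest.approx(vol.data)

    def test_constant_scalar_stays_constant(self):
        vol = ImageVolume(np.full((8, 8, 8), 3.25), SP)
        field, _ = sinusoid_field(2.0, 30.0, (8, 8, 8))
        out = warp_scalar(vol, field)
        assert np.nanmax(np.abs(out.data - 3.25)) < 1e-12

    def test_integer_translation_moves_delta_spike(self):
        data = np.zeros((10, 10, 10))
        data[6, 5, 5] = 1.0
        u = np.zeros((10, 10, 10, 3))
        u[..., 0] = 2 * SP[0]  # sample two voxels ahead along axis 0
        out = warp_scalar(ImageVolume(data, SP), DisplacementField(u, SP))
        assert out.data[4, 5, 5] == pytest.approx(1.0)
        assert np.nansum(out.data) == pytest.approx(1.0)

    def test_out_of_domain_marked_invalid(self):
        u = np.full((6, 6, 6, 3), 100.0)
        out = warp_scalar(ImageVolume(np.ones((6, 6, 6)), SP), DisplacementField(u, SP))
        assert np.all(np.isnan(out.data))


class TestFractionalAirVolumeChange:
    @staticmethod
    def _two_lobes(shape=(8, 8, 8)):
        mask = np.ones(shape, dtype=np.int16)
        mask[4:] = 2
        return LobeMask(mask, SP, labels={"A": 1, "B": 2})

    def test_prescribed_three_to_one_ratio(self):
        lobes = self._two_lobes()
        insp = np.full((8, 8, 8), 0.5)
        exp = insp.copy()
        exp[:4] -= 0.3  # lobe A gains 0.3 of air per voxel toward inspiration
        exp[4:] -= 0.1  # lobe B gains 0.1
        zero = DisplacementField(np.zeros((8, 8, 8, 3)), SP)
        J = np.ones((8, 8, 8))
        out = fractional_air_volume_change(
            FractionMap(insp, SP), FractionMap(exp, SP), zero, J, lobes, exclude_boundary=False
        )
        assert out["A"] == pytest.approx(0.75)
        assert out["B"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self, deforming_phantom):
        b = deforming_phantom
        J = jacobian_determinant(deformation_gradient(b.true_field))
        out = fractional_air_volume_change(
            b.true_beta_air_tlc, b.true_beta_air_exp, b.true_field, J, b.lobe_mask
        )
        assert abs(sum(out.values()) - 1.0) <= 1e-9

    def test_swapped_inputs_rejected(self):
        lobes = self._two_lobes()
        insp = np.full((8, 8, 8), 0.5)
        exp = insp + 0.2  # expiration airier than inspiration: inputs swapped
        zero = DisplacementField(np.zeros((8, 8, 8, 3)), SP)
        with pytest.raises(ValueError, match="swapped"):
            fractional_air_volume_change(
                FractionMap(insp, SP), FractionMap(exp, SP), zero, np.ones((8, 8, 8)), lobes
            )


class TestEstimateDisplacement:
    def _blob(self, center, shape=(32, 32, 32)):
        idx = np.indices(shape, dtype=float)
        r2 = sum(((idx[a] * SP[a] - center[a]) / 18.0) ** 2 for a in range(3))
        return ImageVolume(-800.0 * np.exp(-r2) + 55.0, SP)

    def test_identical_images_give_null_field(self):
        fixed = self._blob((31.0, 31.0, 31.0))
        field = estimate_displacement(fixed, fixed)
        assert np.abs(field.data).max() < 0.1 * SP[0]

    def test_two_voxel_translation_recovered(self):
        fixed = self._blob((31.0, 31.0, 31.0))
        moving = self._blob((35.0, 31.0, 31.0))  # shifted 2 voxels along axis 0
        field = estimate_displacement(fixed, moving)
        inside = fixed.data < -300.0
        epe = np.linalg.norm(field.data - np.array([4.0, 0.0, 0.0]), axis=-1)
        assert epe[inside].mean() < 0.5 * SP[0]

    def test_sinusoid_lobar_jacobian_within_5pct(self, rng):
        shape = (32, 32, 32)
        texture = ndimage.gaussian_filter(rng.normal(0, 300, shape), 2.0) - 700.0
        moving = ImageVolume(texture, SP)
        # cross-axis sinusoid, 2-voxel amplitude: u_i = a sin(2 pi x_{i+1} / L)
        X = world(shape)
        u = np.stack(
            [4.0 * np.sin(2 * np.pi * X[(i + 1) % 3] / 64.0) for i in range(3)], axis=-1
        )
        field_true = DisplacementField(u, SP)
        w = 2 * np.pi / 64.0
        # det(I + S) with cyclic off-diagonal S: 1 + product of the three terms
        J_true = 1.0 + np.prod(
            [4.0 * w * np.cos(2 * np.pi * X[(i + 1) % 3] / 64.0) for i in range(3)], axis=0
        )
        warped = warp_scalar(moving, field_true)
        fixed = ImageVolume(np.nan_to_num(warped.data, nan=-700.0), SP)
        est = estimate_displacement(
            fixed, moving, RegistrationParams(pyramid_levels=3, iterations_per_level=60, smoothing_sigma_mm=1.5)
        )
        J_est = jacobian_determinant(deformation_gradient(est))
        mask = np.zeros(shape, np.int16)
        mask[6:26, 6:26, 6:26] = 1
        lobes = LobeMask(mask, SP, labels={"lung": 1})
        true_mean = lobar_mean(J_true, lobes)["lung"]
        est_mean = lobar_mean(J_est, lobes)["lung"]
        assert abs(est_mean / true_mean - 1.0) < 0.05
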