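"""Registration-derived lung deformation metrics.

Given a displacement field u(x) mapping each expiration-grid point x to its
inspiration-space position x + u(x), the deformation gradient is

    F(x) = I + du/dx,

estimated by spacing-scaled central differences in the interior and one-sided
differences at the boundary.  From F:

* Jacobian determinant ``J = det F`` — local volume expansion factor toward
  inspiration (J > 1: the region inflates);
* principal stretches ``lambda1 >= lambda2 >= lambda3 > 0`` — singular values
  of F (square roots of the eigenvalues of F^T F), insensitive to rotation;
* anisotropic deformation index
  ``ADI = sqrt(((l1 - l2)/l2)^2 + ((l2 - l3)/l3)^2)`` — magnitude of the
  directional preference of the deformation (0 for isotropic or rigid motion);
* fractional lobar air-volume change ``dVair_f`` — each lobe's share of the
  whole-lung air-volume change between expiration and inspiration, computed
  under tissue-mass conservation from J and the two air-fraction maps.

Lobar summaries exclude a one-voxel boundary shell where the one-sided
stencil is first-order only.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import DisplacementField, FractionMap, ImageVolume, LobeMask

__all__ = [
    "deformation_gradient",
    "jacobian_determinant",
    "principal_stretches",
    "adi",
    "adi_from_stretches",
    "lobar_mean",
    "interior_mask",
    "warp_scalar",
    "fractional_air_volume_change",
    "estimate_displacement",
    "RegistrationParams",
]


def deformation_gradient(field: DisplacementField) -> np.ndarray:
    """Per-voxel deformation gradient F = I + grad(u), shape (nx, ny, nz, 3, 3).

    Central differences interiorly, one-sided at the boundary, scaled by the
    grid spacing so derivatives are dimensionless (mm / mm).
    """
    if any(n < 3 for n in field.shape):
        raise ValueError(f"grid must be >= 3 voxels per axis, got {field.shape}")
    nx, ny, nz = field.shape
    F = np.zeros((nx, ny, nz, 3, 3), dtype=float)
    for i in range(3):
        grads = np.gradient(field.data[..., i], *field.spacing, edge_order=1)
        for j in range(3):
            F[..., i, j] = grads[j]
        F[..., i, i] += 1.0
    return F


def jacobian_determinant(tensors: np.ndarray, lung: np.ndarray | None = None) -> np.ndarray:
    """J = det F per voxel; warns if folding (J <= 0) occurs inside the lung."""
    J = np.linalg.det(tensors)
    check = J if lung is None else J[lung]
    n_fold = int(np.count_nonzero(check <= 0))
    if n_fold:
        import warnings

        warnings.warn(
            f"{n_fold} voxels with non-positive Jacobian (registration folding)",
            RuntimeWarning,
            stacklevel=2,
        )
    return J


def principal_stretches(tensors: np.ndarray) -> np.ndarray:
    """Principal stretches per voxel, sorted descending (l1 >= l2 >= l3).

    Singular values of F, i.e. square roots of the eigenvalues of F^T F,
    so pure rotations yield (1, 1, 1).
    """
    return np.linalg.svd(tensors, compute_uv=False)


def adi(tensors: np.ndarray) -> np.ndarray:
    """Anisotropic deformation index per voxel from deformation-gradient tensors."""
    return adi_from_stretches(principal_stretches(np.asarray(tensors, dtype=float)))


def adi_from_stretches(stretches: np.ndarray) -> np.ndarray:
    """ADI from principal stretches (trailing axis of length 3, any order)."""
    lam = np.sort(np.asarray(stretches, dtype=float), axis=-1)[..., ::-1]
    if np.any(lam[..., 2] <= 0):
        raise ValueError("non-positive principal stretch (degenerate deformation)")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    return np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)


def interior_mask(shape: tuple[int, ...], margin: int = 1) -> np.ndarray:
    """True away from the grid boundary (central-difference stencil region)."""
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, n - margin) for n in shape)
    m[sl] = True
    return m


def lobar_mean(values: np.ndarray, lobes: LobeMask, exclude_boundary: bool = True) -> dict[str, float]:
    """Mean of a voxel field over each lobe, boundary shell excluded."""
    keep = interior_mask(values.shape) if exclude_boundary else np.ones(values.shape, bool)
    keep &= np.isfinite(values)
    out = {}
    for name in lobes.labels:
        sel = lobes.lobe(name) & keep
        out[name] = float(values[sel].mean()) if sel.any() else float("nan")
    lung = lobes.lung() & keep
    out["whole_lung"] = float(values[lung].mean()) if lung.any() else float("nan")
    return out


def warp_scalar(map_on_insp_grid: ImageVolume, field: DisplacementField) -> FractionMap:
    """Pull an inspiration-grid scalar back onto the expiration grid.

    Samples the scalar at x + u(x) with trilinear interpolation.  Samples
    falling outside the inspiration domain are returned as NaN and excluded
    from downstream voxel counts.
    """
    nx, ny, nz = field.shape
    idx = np.indices((nx, ny, nz), dtype=float)
    coords = np.empty((3, nx, ny, nz))
    for ax in range(3):
        world = field.origin[ax] + idx[ax] * field.spacing[ax] + field.data[..., ax]
        coords[ax] = (world - map_on_insp_grid.origin[ax]) / map_on_insp_grid.spacing[ax]
    warped = ndimage.map_coordinates(
        np.asarray(map_on_insp_grid.data, dtype=float), coords, order=1, mode="constant", cval=np.nan
    )
    shape_in = map_on_insp_grid.data.shape
    inside = np.ones((nx, ny, nz), dtype=bool)
    for ax in range(3):
        inside &= (coords[ax] >= 0) & (coords[ax] <= shape_in[ax] - 1)
    warped[~inside] = np.nan
    return FractionMap(warped, field.spacing, field.origin)


def fractional_air_volume_change(
    insp_beta_air: FractionMap,
    exp_beta_air: FractionMap,
    field: DisplacementField,
    J: np.ndarray,
    lobes: LobeMask,
    exclude_boundary: bool = True,
) -> dict[str, float]:
    """Fractional lobar air-volume change dVair_f: each lobe's share of the
    whole-lung air-volume gain from expiration to inspiration.

    Per expiration-grid voxel of volume v, the air-volume change is
    ``v * (J * beta_air_insp(x + u(x)) - beta_air_exp(x))``: the voxel's
    material occupies volume J*v at inspiration with the warped inspiratory
    air fraction.  Lobar sums are normalised by the whole-lung sum, so the
    returned fractions add to 1.
    """
    warped = warp_scalar(insp_beta_air, field)
    valid = np.isfinite(warped.data) & np.isfinite(exp_beta_air.data) & np.isfinite(J)
    if exclude_boundary:
        valid &= interior_mask(J.shape)
    dv = J * warped.data - exp_beta_air.data  # per unit voxel volume
    lobe_sums = {}
    for name in lobes.labels:
        sel = lobes.lobe(name) & valid
        lobe_sums[name] = float(dv[sel].sum()) if sel.any() else 0.0
    total = sum(lobe_sums.values())
    if total <= 0:
        raise ValueError(
            "total lung air-volume change is non-positive; inspiration and "
            "expiration inputs are likely swapped"
        )
    return {name: s / total for name, s in lobe_sums.items()}


class RegistrationParams:
    """Parameters for the bundled demons estimator.

    A deliberately simple multi-resolution, diffusion-regularised (demons)
    registration; any externally estimated field in the same format may be
    substituted for production use.
    """

    def __init__(
        self,
        pyramid_levels: int = 3,
        iterations_per_level: int = 50,
        smoothing_sigma_mm: float = 2.0,
    ) -> None:
        self.pyramid_levels = int(pyramid_levels)
        self.iterations_per_level = int(iterations_per_level)
        self.smoothing_sigma_mm = float(smoothing_sigma_mm)


def estimate_displacement(
    fixed: ImageVolume,
    moving: ImageVolume,
    params: RegistrationParams | None = None,
) -> DisplacementField:
    """Estimate the expiration->inspiration displacement field by demons
    registration (fixed = expiration, moving = inspiration).

    Deterministic given the inputs and parameters.  Raises if the
    registration diverges (mean squared dissimilarity increases).
    """
    import SimpleITK as sitk

    if fixed.data.shape != moving.data.shape:
        raise ValueError("fixed and moving volumes must share a grid")
    params = params or RegistrationParams()

    def to_sitk(vol: ImageVolume) -> "sitk.Image":
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T, dtype=np.float64))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        return img

    f_img, m_img = to_sitk(fixed), to_sitk(moving)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(params.iterations_per_level)
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(params.smoothing_sigma_mm)

    shrinks = [2**lvl for lvl in reversed(range(params.pyramid_levels))]
    disp = None
    for shrink in shrinks:
        if shrink > 1:
            f_lvl = sitk.Shrink(f_img, [shrink] * 3)
            m_lvl = sitk.Shrink(m_img, [shrink] * 3)
        else:
            f_lvl, m_lvl = f_img, m_img
        if disp is None:
            disp = sitk.Image(f_lvl.GetSize(), sitk.sitkVectorFloat64, 3)
            disp.CopyInformation(f_lvl)
        else:
            disp = sitk.Resample(disp, f_lvl, sitk.Transform(), sitk.sitkLinear)
        disp = demons.Execute(f_lvl, m_lvl, disp)
    disp = sitk.Resample(disp, f_img, sitk.Transform(), sitk.sitkLinear)

    u = sitk.GetArrayFromImage(disp)  # (z, y, x, 3), components in world (x, y, z)
    u = np.transpose(u, (2, 1, 0, 3))
    result = DisplacementField(u, fixed.spacing, fixed.origin)

    # divergence check on in-domain voxels only
    warped = warp_scalar(moving, result)
    valid = np.isfinite(warped.data)
    before = float(np.mean((fixed.data[valid] - moving.data[valid]) ** 2))
    after = float(np.mean((warped.data[valid] - fixed.data[valid]) ** 2))
    if before > 0 and after > before * 1.05:
        raise RuntimeError(
            f"registration diverged: dissimilarity rose from {before:.4g} to {after:.4g}"
        )
    return result
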