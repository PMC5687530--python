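"""Fraction-threshold lung densitometry.

HU values are converted to a per-voxel air fraction

    beta_air = (hu_tissue - HU) / (hu_tissue - hu_air),   clamped to [0, 1],

with ``beta_tissue = 1 - beta_air``.  Disease percentages are then defined by
thresholds on the *fraction* rather than on raw HU, which removes scanner /
site calibration offsets that scale with the air-tissue HU span:

* ``Emph%``  — percent of inspiratory lung voxels with beta_air > 0.985
  (emphysema-like, near-total air content);
* ``fSAD%``  — functional small-airway disease: percent of expiratory lung
  voxels that are air-trapped (beta_air > 0.90) *and* not emphysematous on
  the registered inspiratory scan (warped inspiratory beta_air <= 0.985),
  the parametric-response-map subtraction;
* ``beta_tissue`` — mean tissue fraction per lobe at inspiration.

With the default references (air -1000 HU, soft tissue +55 HU) the fraction
thresholds correspond to HU cutoffs of -984.175 (emphysema) and -894.5
(air trapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import FractionMap, ImageVolume, LobeMask

WHOLE_LUNG = "whole_lung"


@dataclass(frozen=True)
class DensitometryRefs:
    """Reference HU values and fraction thresholds.

    hu_air / hu_tissue are the pure-air and pure-soft-tissue references used
    to linearly map HU to an air fraction; thresholds are on beta_air.
    """

    hu_air: float = -1000.0
    hu_tissue: float = 55.0
    emph_threshold: float = 0.985
    fsad_threshold: float = 0.90
    expiration_state: str = "FRC"  # recorded for reporting only (FRC vs RV)

    def __post_init__(self) -> None:
        if not self.hu_air < self.hu_tissue:
            raise ValueError("hu_air must be below hu_tissue")
        for name in ("emph_threshold", "fsad_threshold"):
            t = getattr(self, name)
            if not 0.0 < t < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {t}")
        if not self.fsad_threshold < self.emph_threshold:
            raise ValueError("fsad_threshold must be below emph_threshold")

    def hu_cutoff(self, beta_air_threshold: float) -> float:
        """HU value equivalent to a beta_air threshold (algebraic inversion)."""
        return self.hu_tissue - beta_air_threshold * (self.hu_tissue - self.hu_air)

    def beta_air_from_hu(self, hu: np.ndarray) -> np.ndarray:
        beta = (self.hu_tissue - np.asarray(hu, dtype=float)) / (self.hu_tissue - self.hu_air)
        return np.clip(beta, 0.0, 1.0)

    def hu_from_beta_air(self, beta_air: np.ndarray) -> np.ndarray:
        """Inverse map, used by the phantom generator to synthesise HU."""
        return self.hu_tissue - np.asarray(beta_air, dtype=float) * (self.hu_tissue - self.hu_air)


def air_fraction(volume: ImageVolume, refs: DensitometryRefs = DensitometryRefs()) -> FractionMap:
    """Per-voxel air fraction beta_air in [0, 1] from an HU volume."""
    return volume.copy_with(refs.beta_air_from_hu(volume.data))


def tissue_fraction(beta_air: FractionMap) -> FractionMap:
    """Complementary tissue fraction: beta_tissue = 1 - beta_air (exact)."""
    return beta_air.copy_with(1.0 - beta_air.data)


def _check_aligned(a, b, what: str) -> None:
    if tuple(a.data.shape[:3]) != tuple(b.data.shape[:3]):
        raise ValueError(f"{what}: grid shape mismatch {a.data.shape[:3]} vs {b.data.shape[:3]}")


def _per_lobe_percent(numer_mask: np.ndarray, valid: np.ndarray, lobes: LobeMask) -> dict[str, float]:
    out: dict[str, float] = {}
    lung = lobes.lung() & valid
    if not lung.any():
        raise ValueError("empty lung mask (no labelled voxels)")
    for name in lobes.labels:
        sel = lobes.lobe(name) & valid
        if not sel.any():
            raise ValueError(f"lobe {name!r} has no voxels in the mask")
        out[name] = 100.0 * float(np.count_nonzero(numer_mask & sel)) / float(np.count_nonzero(sel))
    out[WHOLE_LUNG] = 100.0 * float(np.count_nonzero(numer_mask & lung)) / float(np.count_nonzero(lung))
    return out


def emphysema_percent(
    insp_beta_air: FractionMap,
    lobes: LobeMask,
    refs: DensitometryRefs = DensitometryRefs(),
) -> dict[str, float]:
    """Emph% per lobe and whole lung on the inspiration grid.

    100 x (# masked voxels with beta_air > emph_threshold) / (# masked voxels).
    """
    _check_aligned(insp_beta_air, lobes, "emphysema_percent")
    above = insp_beta_air.data > refs.emph_threshold
    valid = np.isfinite(insp_beta_air.data)
    return _per_lobe_percent(above, valid, lobes)


def fsad_percent(
    exp_beta_air: FractionMap,
    warped_insp_beta_air: FractionMap,
    lobes: LobeMask,
    refs: DensitometryRefs = DensitometryRefs(),
) -> dict[str, float]:
    """fSAD% per lobe and whole lung on the expiration grid.

    Air-trapped voxels (expiratory beta_air > fsad_threshold) minus those
    already emphysematous on the co-registered inspiratory map (warped
    inspiratory beta_air > emph_threshold).  NaNs in the warped map mark
    voxels whose pull-back sample fell outside the inspiration domain; they
    are excluded from numerator and denominator.
    """
    _check_aligned(exp_beta_air, lobes, "fsad_percent")
    _check_aligned(exp_beta_air, warped_insp_beta_air, "fsad_percent")
    valid = np.isfinite(exp_beta_air.data) & np.isfinite(warped_insp_beta_air.data)
    trapped = exp_beta_air.data > refs.fsad_threshold
    emph_at_insp = warped_insp_beta_air.data > refs.emph_threshold
    numer = trapped & ~emph_at_insp & valid
    return _per_lobe_percent(numer, valid, lobes)


def lobar_tissue_fraction(insp_beta_tissue: FractionMap, lobes: LobeMask) -> dict[str, float]:
    """Mean beta_tissue over each lobe (and whole lung) at inspiration."""
    _check_aligned(insp_beta_tissue, lobes, "lobar_tissue_fraction")
    out: dict[str, float] = {}
    for name in lobes.labels:
        sel = lobes.lobe(name)
        if not sel.any():
            raise ValueError(f"lobe {name!r} is empty")
        out[name] = float(np.nanmean(insp_beta_tissue.data[sel]))
    lung = lobes.lung()
    out[WHOLE_LUNG] = float(np.nanmean(insp_beta_tissue.data[lung]))
    return out
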