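"""Synthetic phantom and cohort generation with exact ground truth.

This module fabricates every input the analysis consumes, with the quantity
each metric measures *prescribed by construction* so downstream modules can
be validated against known truth:

* paired inspiration (TLC) / expiration HU volumes on a shared grid, linked
  by a known smooth displacement field, with per-lobe emphysema and
  air-trapping fractions placed exactly;
* per-branch airway tables covering the 10 analysed regions, generated from
  a known linear tracheal size model on sex/age/height;
* per-subject metric tables for three cohorts (healthy / asthma / COPD)
  whose group shifts are configurable per metric.

Geometry is deliberately schematic: the five lobes are disjoint axis-aligned
blocks, which keeps voxel counts, fractions and deformation ground truth
exact and the tests fast.  The expiration image is the inspiration image
pulled back through the prescribed field with tissue-mass-consistent
intensity rescaling (``beta_tissue_exp = J * beta_tissue_insp(x + u(x))``);
air-trapped voxels then override this with a high retained air fraction —
trapping *is* a local departure from uniform deflation.  Additive Gaussian
HU noise is applied last, after all ground-truth bookkeeping.

All randomness derives from a single seed fanned out into named substreams,
so adding a component never perturbs earlier draws and identical configs are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airway import AIRWAY_REGIONS
from .densitometry import DensitometryRefs
from .deformation import warp_scalar
from .images import DisplacementField, FractionMap, ImageVolume, LobeMask, LOBE_LABELS
from .stats import GROUPS

# ---------------------------------------------------------------------------
# deterministic substreams

_STREAMS = {
    "noise_tlc": 0,
    "noise_exp": 1,
    "demographics": 2,
    "airway": 3,
    "metrics": 4,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    key = (_STREAMS[stream],) + tuple(int(e) for e in extra)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


# ---------------------------------------------------------------------------
# phantom image pair

#: Default lobe layout on a 32^3 grid: ((i0, i1), (j0, j1), (k0, k1)) blocks.
DEFAULT_LOBE_LAYOUT: dict[str, tuple[tuple[int, int], ...]] = {
    "LUL": ((4, 15), (6, 26), (16, 28)),
    "LLL": ((4, 15), (6, 26), (4, 16)),
    "RUL": ((17, 28), (6, 26), (20, 28)),
    "RML": ((17, 28), (6, 26), (14, 20)),
    "RLL": ((17, 28), (6, 26), (4, 14)),
}


@dataclass
class DeformationSpec:
    """Prescribed analytic expiration->inspiration displacement.

    ``u(x) = (A - I)(x - c) + a_i * sin(2 pi x_{m(i)} / L_i)`` with c the grid
    centre and m(i) = (i+1) mod 3 (cross-axis sinusoid, so the gradient has
    off-diagonal structure).  Amplitudes must keep the displacement-gradient
    spectral norm below 1 so the mapping is invertible.
    """

    affine: np.ndarray | None = None          # 3x3; None = identity
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sin_amplitude_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sin_period_mm: tuple[float, float, float] = (64.0, 64.0, 64.0)

    def matrix(self) -> np.ndarray:
        return np.eye(3) if self.affine is None else np.asarray(self.affine, dtype=float)


def uniform_expansion(volume_ratio: float) -> np.ndarray:
    """Isotropic affine matrix with det = volume_ratio (TLC/expiration)."""
    return np.eye(3) * float(volume_ratio) ** (1.0 / 3.0)


@dataclass
class PhantomConfig:
    """Everything needed to generate one subject's phantom scan pair."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lobe_layout: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_LOBE_LAYOUT.items()}
    )
    target_emph_pct: dict[str, float] | float = 0.0
    target_fsad_pct: dict[str, float] | float = 0.0
    deformation_spec: DeformationSpec = field(
        default_factory=lambda: DeformationSpec(
            affine=uniform_expansion(1.3), sin_amplitude_mm=(1.5, 1.5, 1.5)
        )
    )
    noise_sd_hu: float = 20.0
    seed: int = 0
    # air fractions assigned to the three tissue classes (before deformation)
    parenchyma_beta_insp: float = 0.88
    emph_beta_insp: float = 0.995
    fsad_beta_exp: float = 0.95
    refs: DensitometryRefs = field(default_factory=DensitometryRefs)

    def per_lobe(self, target) -> dict[str, float]:
        if isinstance(target, dict):
            return {lobe: float(target.get(lobe, 0.0)) for lobe in self.lobe_layout}
        return {lobe: float(target) for lobe in self.lobe_layout}

    def validate(self) -> None:
        if any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape axes must be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        occupancy = np.zeros(self.grid_shape, dtype=np.int8)
        for lobe, block in self.lobe_layout.items():
            sl = tuple(slice(a, b) for a, b in block)
            occupancy[sl] += 1
        if occupancy.max() > 1:
            raise ValueError("lobe blocks overlap; the layout must be disjoint")
        emph = self.per_lobe(self.target_emph_pct)
        fsad = self.per_lobe(self.target_fsad_pct)
        for lobe in self.lobe_layout:
            e, f = emph[lobe], fsad[lobe]
            if not (0 <= e <= 100 and 0 <= f <= 100 and e + f <= 100):
                raise ValueError(f"lobe {lobe}: emph% {e} + fsad% {f} must fit in [0, 100]")


@dataclass
class PhantomBundle:
    """Generated pair plus every piece of ground truth used to make it."""

    tlc_volume: ImageVolume
    exp_volume: ImageVolume
    lobe_mask: LobeMask
    true_field: DisplacementField
    true_beta_air_tlc: FractionMap
    true_beta_air_exp: FractionMap
    true_jacobian: np.ndarray
    true_lobar_air_change_frac: dict[str, float]
    config: PhantomConfig


def _grid_world(shape, spacing) -> list[np.ndarray]:
    idx = np.indices(shape, dtype=float)
    return [idx[a] * spacing[a] for a in range(3)]


def _analytic_field(spec: DeformationSpec, shape, spacing):
    """Displacement u, deformation gradient F and det F, all analytic."""
    X = _grid_world(shape, spacing)
    centre = [0.5 * (n - 1) * s for n, s in zip(shape, spacing)]
    A = spec.matrix()
    u = np.zeros(shape + (3,))
    F = np.broadcast_to(A, shape + (3, 3)).copy()
    for i in range(3):
        u[..., i] += spec.translation_mm[i]
        for j in range(3):
            u[..., i] += (A[i, j] - (1.0 if i == j else 0.0)) * (X[j] - centre[j])
        m = (i + 1) % 3
        a, L = spec.sin_amplitude_mm[i], spec.sin_period_mm[i]
        if a != 0.0:
            phase = 2.0 * np.pi * X[m] / L
            u[..., i] += a * np.sin(phase)
            F[..., i, m] += a * (2.0 * np.pi / L) * np.cos(phase)
    J = np.linalg.det(F)
    return u, F, J


def _check_invertible(spec: DeformationSpec, shape, spacing) -> None:
    _, F, J = _analytic_field(spec, shape, spacing)
    gradu = F - np.eye(3)
    norms = np.linalg.svd(gradu, compute_uv=False)[..., 0]
    if norms.max() >= 1.0 or J.min() <= 0.0:
        raise ValueError(
            "deformation_spec is not invertible: max displacement-gradient norm "
            f"{norms.max():.3f} (must be < 1), min Jacobian {J.min():.3f} (must be > 0)"
        )


def _class_slabs(block, n_lo: int, n_hi: int, shape):
    """Flat indices of the first n_lo and last n_hi voxels of a block in
    lexicographic order (contiguous slabs at opposite ends)."""
    ii = np.arange(block[0][0], block[0][1])
    jj = np.arange(block[1][0], block[1][1])
    kk = np.arange(block[2][0], block[2][1])
    I, Jx, K = np.meshgrid(ii, jj, kk, indexing="ij")
    flat = np.ravel_multi_index((I.ravel(), Jx.ravel(), K.ravel()), shape)
    lo = flat[:n_lo]
    hi = flat[len(flat) - n_hi:] if n_hi > 0 else flat[:0]
    return flat, lo, hi


def generate_phantom_pair(config: PhantomConfig) -> PhantomBundle:
    """Generate a paired TLC/expiration phantom with exact ground truth.

    Emphysema voxels are placed on the inspiration grid (where Emph% is
    measured) and air-trapping voxels on the expiration grid (where fSAD% is
    measured), each as contiguous slabs at opposite ends of every lobe with
    exactly ``round(pct/100 * lobe voxel count)`` voxels, so the prescribed
    percentages are recovered exactly on a deformation-free, noise-free
    phantom and to within interface interpolation error otherwise.
    """
    config.validate()
    _check_invertible(config.deformation_spec, config.grid_shape, config.spacing_mm)
    shape, spacing = tuple(config.grid_shape), tuple(config.spacing_mm)
    refs = config.refs

    mask = np.zeros(shape, dtype=np.int16)
    for lobe, block in config.lobe_layout.items():
        mask[tuple(slice(a, b) for a, b in block)] = LOBE_LABELS[lobe]
    lobe_mask = LobeMask(mask, spacing, labels={k: LOBE_LABELS[k] for k in config.lobe_layout})

    emph_pct = config.per_lobe(config.target_emph_pct)
    fsad_pct = config.per_lobe(config.target_fsad_pct)

    # inspiration air-fraction map: parenchyma + exact emphysema slabs
    beta_insp = np.zeros(shape)
    beta_insp[mask > 0] = config.parenchyma_beta_insp
    fsad_voxels: dict[str, np.ndarray] = {}
    for lobe, block in config.lobe_layout.items():
        n_vox = int(np.prod([b - a for a, b in block]))
        n_e = int(round(emph_pct[lobe] / 100.0 * n_vox))
        n_f = int(round(fsad_pct[lobe] / 100.0 * n_vox))
        _, lo, hi = _class_slabs(block, n_e, n_f, shape)
        beta_insp.ravel()[lo] = config.emph_beta_insp
        fsad_voxels[lobe] = hi  # trapped class lives on the expiration grid

    u, _, J = _analytic_field(config.deformation_spec, shape, spacing)
    field_true = DisplacementField(u, spacing)

    # mass-consistent pull-back: beta_tissue_exp = J * beta_tissue_insp(x+u)
    insp_map = FractionMap(beta_insp, spacing)
    warped_insp = warp_scalar(insp_map, field_true)
    wdata = warped_insp.data.copy()
    outside = ~np.isfinite(wdata)
    wdata[outside] = 0.0  # beyond the image: chest-wall-like tissue (beta_air 0)
    beta_exp = 1.0 - J * (1.0 - wdata)
    np.clip(beta_exp, 0.0, 1.0, out=beta_exp)

    # air trapping: retained air at expiration, overriding uniform deflation
    for lobe, flat in fsad_voxels.items():
        beta_exp.ravel()[flat] = config.fsad_beta_exp

    # ground-truth lobar air-volume change, booked from the air the phantom
    # actually contains: per voxel J * beta_air_insp(x+u) - beta_air_exp,
    # with the analytic Jacobian.  In the clamp- and override-free interior
    # this reduces to (J - 1) by tissue-mass conservation.
    change_vox = np.where(outside, 0.0, J * wdata - beta_exp)
    lobe_change = {}
    for lobe in config.lobe_layout:
        sel = mask == LOBE_LABELS[lobe]
        lobe_change[lobe] = float(np.sum(change_vox[sel]))
    total = sum(lobe_change.values())
    true_frac = (
        {lobe: v / total for lobe, v in lobe_change.items()} if total > 0 else
        {lobe: float("nan") for lobe in lobe_change}
    )

    hu_tlc = refs.hu_from_beta_air(beta_insp)
    hu_exp = refs.hu_from_beta_air(beta_exp)
    if config.noise_sd_hu > 0:
        hu_tlc = hu_tlc + _rng(config.seed, "noise_tlc").normal(0.0, config.noise_sd_hu, shape)
        hu_exp = hu_exp + _rng(config.seed, "noise_exp").normal(0.0, config.noise_sd_hu, shape)

    return PhantomBundle(
        tlc_volume=ImageVolume(hu_tlc, spacing),
        exp_volume=ImageVolume(hu_exp, spacing),
        lobe_mask=lobe_mask,
        true_field=field_true,
        true_beta_air_tlc=FractionMap(beta_insp, spacing),
        true_beta_air_exp=FractionMap(beta_exp, spacing),
        true_jacobian=J,
        true_lobar_air_change_frac=true_frac,
        config=config,
    )


# ---------------------------------------------------------------------------
# cohorts: airway tables and metric tables

#: True coefficients of the tracheal size model used by the airway generator:
#: value = b0 + b_sex*sex + b_age*age + b_height*height   (sex: 1 = male).
TRACHEA_DH_COEF = np.array([6.0, 2.5, -0.01, 0.07])
TRACHEA_WT_COEF = np.array([0.5, 0.30, 0.002, 0.010])

#: Mean airway size per region relative to the trachea.
REGION_SCALE: dict[str, float] = {
    "trachea": 1.0, "RMB": 0.85, "LMB": 0.75, "BronInt": 0.65, "TriLLB": 0.55,
    "sLUL": 0.35, "sRUL": 0.35, "sRML": 0.32, "sLLL": 0.35, "sRLL": 0.35,
}
_BRANCHES_PER_REGION = {r: (1 if r in AIRWAY_REGIONS[:5] else 3) for r in AIRWAY_REGIONS}

#: Group age distributions (years): mean, sd — COPD cohorts skew older.
_AGE_BY_GROUP = {"healthy": (50.7, 17.2), "asthma": (48.7, 11.2), "COPD": (67.1, 7.2)}

LOBES: tuple[str, ...] = tuple(LOBE_LABELS)

#: Baselines for the 9 analysed metrics: (regions, healthy mean, healthy sd).
#: dVair_f uses per-lobe means (normalised per subject to sum to 1).
METRIC_BASELINES: dict[str, tuple[tuple[str, ...], object, float]] = {
    "Cr": (AIRWAY_REGIONS, 0.92, 0.03),
    "WT_star": (AIRWAY_REGIONS, 1.0, 0.08),
    "Dh_star": (AIRWAY_REGIONS, REGION_SCALE, 0.05),
    "Emph_pct": (LOBES, 1.5, 1.5),
    "fSAD_pct": (LOBES, 5.0, 4.0),
    "beta_tissue": (LOBES, 0.15, 0.02),
    "dVair_f": (LOBES, {"LUL": 0.22, "LLL": 0.22, "RUL": 0.18, "RML": 0.08, "RLL": 0.30}, 0.03),
    "Jacobian": (LOBES, 2.2, 0.25),
    "ADI": (LOBES, 0.8, 0.12),
}

#: Default group effects: location shift (metric units) and sd scale factor.
#: Directions follow the disease pattern: denser emphysema / trapping and
#: weaker deformation in COPD than asthma than healthy; airway narrowing and
#: reduced circularity in both disease groups.
DEFAULT_EFFECT_TABLE: dict[str, dict[str, dict[str, float]]] = {
    "Cr": {"asthma": {"shift": -0.03}, "COPD": {"shift": -0.05}},
    "WT_star": {"COPD": {"shift": 0.05}},
    "Dh_star": {"asthma": {"shift": -0.05}, "COPD": {"shift": -0.05}},
    "Emph_pct": {"asthma": {"shift": 1.5, "scale": 1.5}, "COPD": {"shift": 7.5, "scale": 3.0}},
    "fSAD_pct": {"asthma": {"shift": 5.0, "scale": 1.25}, "COPD": {"shift": 13.0, "scale": 1.5}},
    "beta_tissue": {"COPD": {"shift": -0.03}},
    "dVair_f": {},
    "Jacobian": {"asthma": {"shift": -0.25}, "COPD": {"shift": -0.6}},
    "ADI": {"asthma": {"shift": -0.06}, "COPD": {"shift": -0.15}},
}


@dataclass
class CohortConfig:
    """Three-cohort generator settings.

    ``n_per_group`` may be one integer (balanced design) or a mapping
    group -> n.  ``effect_table`` entries are {metric: {group: {"shift": s,
    "scale": c}}}; shift is additive in metric units, scale multiplies the
    healthy sd.  ``baselines`` may replace the default 9-metric layout, e.g.
    for pure simulation families.
    """

    n_per_group: int | dict[str, int] = 50
    effect_table: dict = field(default_factory=lambda: DEFAULT_EFFECT_TABLE)
    baselines: dict = field(default_factory=lambda: METRIC_BASELINES)
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_group, dict):
            sizes = {g: int(self.n_per_group.get(g, 0)) for g in GROUPS}
        else:
            sizes = {g: int(self.n_per_group) for g in GROUPS}
        for g, n in sizes.items():
            if n < 3:
                raise ValueError(f"n_per_group must be >= 3 per group, got {n} for {g}")
        return sizes

    def validate(self) -> None:
        self.group_sizes()
        unknown_metrics = set(self.effect_table) - set(self.baselines)
        if unknown_metrics:
            raise ValueError(f"effect_table references unknown metrics: {sorted(unknown_metrics)}")
        for metric, per_group in self.effect_table.items():
            unknown_groups = set(per_group) - set(GROUPS)
            if unknown_groups:
                raise ValueError(f"effect_table[{metric!r}] has unknown groups: {sorted(unknown_groups)}")


def null_family_config(
    n_tests: int = 87,
    n_per_group: int | dict[str, int] = 50,
    seed: int = 0,
) -> CohortConfig:
    """A global-null cohort whose omnibus family has exactly ``n_tests`` tests:
    ``n_tests`` independent standard-normal variables, no group shifts."""
    baselines = {f"var_{i:03d}": (("global",), 0.0, 1.0) for i in range(1, n_tests + 1)}
    return CohortConfig(n_per_group=n_per_group, effect_table={}, baselines=baselines, seed=seed)


def _demographics(config: CohortConfig) -> pd.DataFrame:
    rows = []
    sizes = config.group_sizes()
    sid = 0
    for gi, group in enumerate(GROUPS):
        rng = _rng(config.seed, "demographics", gi)
        mu, sd = _AGE_BY_GROUP[group]
        for _ in range(sizes[group]):
            sex = int(rng.random() < 0.5)
            age = float(np.clip(rng.normal(mu, sd), 20, 90))
            height = float(rng.normal(178.0 if sex else 164.0, 7.0))
            rows.append(
                {"subject_id": f"S{sid:04d}", "group": group, "sex": sex,
                 "age": age, "height": height}
            )
            sid += 1
    return pd.DataFrame(rows)


def generate_airway_table(config: CohortConfig) -> pd.DataFrame:
    """Per-branch airway records for every subject and all 10 regions.

    Branch lumen geometry is derived from a per-subject tracheal hydraulic
    diameter following the known linear model on sex/age/height, scaled per
    region, with group effects applied as fractional Dh shifts and additive
    Cr shifts from the effect table.  A and P are back-computed from the
    target Dh and Cr (P = pi Dh / Cr, A = pi Dh^2 / (4 Cr)), so the
    isoperimetric constraint holds by construction.
    """
    config.validate()
    demo = _demographics(config)
    cr_effects = config.effect_table.get("Cr", {})
    dh_effects = config.effect_table.get("Dh_star", {})
    wt_effects = config.effect_table.get("WT_star", {})
    rows = []
    for si, subj in demo.iterrows():
        rng = _rng(config.seed, "airway", si)
        x = np.array([1.0, subj.sex, subj.age, subj.height])
        dh_trachea = float(TRACHEA_DH_COEF @ x) + rng.normal(0.0, 0.5)
        wt_trachea = float(TRACHEA_WT_COEF @ x) + rng.normal(0.0, 0.1)
        dh_shift = float(dh_effects.get(subj.group, {}).get("shift", 0.0))
        wt_shift = float(wt_effects.get(subj.group, {}).get("shift", 0.0))
        cr_shift = float(cr_effects.get(subj.group, {}).get("shift", 0.0))
        for region in AIRWAY_REGIONS:
            for _ in range(_BRANCHES_PER_REGION[region]):
                dh = dh_trachea * REGION_SCALE[region] * (1.0 + dh_shift + rng.normal(0.0, 0.05))
                wt = wt_trachea * max(REGION_SCALE[region], 0.5) * (1.0 + wt_shift + rng.normal(0.0, 0.05))
                cr = float(np.clip(0.92 + cr_shift + rng.normal(0.0, 0.03), 0.5, 1.0))
                dh = max(dh, 0.5)
                perimeter = np.pi * dh / cr
                area = np.pi * dh**2 / (4.0 * cr)
                rows.append(
                    {"subject_id": subj.subject_id, "group": subj.group,
                     "sex": subj.sex, "age": subj.age, "height": subj.height,
                     "region": region, "lumen_area_mm2": area,
                     "lumen_perimeter_mm": perimeter, "wall_thickness_mm": max(wt, 0.05)}
                )
    return pd.DataFrame(rows)


def generate_cohort_metrics(config: CohortConfig) -> pd.DataFrame:
    """Per-subject per-region values for every metric in the baseline table.

    Values are Gaussian around the healthy baseline with group-specific
    location shift and sd scale; percentage metrics are clipped at 0 and
    fractions to [0, 1] (identically across groups, preserving
    exchangeability under the global null).  ``dVair_f`` draws are
    renormalised per subject so lobar fractions sum to 1.
    """
    config.validate()
    demo = _demographics(config)
    n_subj = len(demo)
    groups = demo["group"].to_numpy()
    frames = []
    for mi, metric in enumerate(config.baselines):
        regions, base, sd = config.baselines[metric]
        regions = tuple(regions)
        effects = config.effect_table.get(metric, {})
        # one substream per metric: adding a metric never perturbs the others
        rng = _rng(config.seed, "metrics", mi)
        z = rng.standard_normal((n_subj, len(regions)))
        mu = np.array(
            [base[r] if isinstance(base, dict) else float(base) for r in regions]
        )[None, :]
        shift = np.array(
            [float(effects.get(g, {}).get("shift", 0.0)) for g in groups]
        )[:, None]
        scale = np.array(
            [float(effects.get(g, {}).get("scale", 1.0)) for g in groups]
        )[:, None]
        values = mu + shift + scale * sd * z
        if metric.endswith("_pct"):
            np.clip(values, 0.0, None, out=values)
        elif metric in ("beta_tissue", "dVair_f"):
            np.clip(values, 0.0, 1.0, out=values)
        if metric == "dVair_f":
            totals = values.sum(axis=1, keepdims=True)
            np.divide(values, totals, out=values, where=totals > 0)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(demo["subject_id"].to_numpy(), len(regions)),
                    "group": np.repeat(groups, len(regions)),
                    "metric": metric,
                    "region": np.tile(regions, n_subj),
                    "value": values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
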