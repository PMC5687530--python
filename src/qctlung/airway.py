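"""Airway morphometry: circularity, hydraulic diameter, wall thickness and
their normalisation by healthy-predicted tracheal values.

Per-branch inputs are the lumen cross-sectional area A (mm^2), lumen
perimeter P (mm) and wall thickness WT (mm), as produced by airway
segmentation software.  Derived quantities:

* circularity   ``Cr = 4 pi A / P^2`` in (0, 1], 1 only for a circle —
  the squared ratio of the hydraulic diameter to the diameter of the circle
  with the same perimeter; lower values mean a more heterogeneous lumen shape;
* hydraulic diameter ``Dh = 4 A / P`` (mm) — luminal calibre measure;
* starred (normalised) values ``Dh* = Dh / Dh_trachea_pred`` and
  ``WT* = WT / WT_trachea_pred``, where the tracheal predictions come from a
  linear (OLS) model on sex, age and height fitted to healthy subjects only.
  Sex dominates inter-subject airway size, so dividing by the predicted
  healthy tracheal value removes the subject-size factor and makes values
  comparable across subjects.

Branch values are aggregated to 10 named regions (five central airways:
trachea, RMB, LMB, BronInt, TriLLB; five segmental groups: sLUL, sRUL, sRML,
sLLL, sRLL) as unweighted means per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 10 analysed airway regions: 5 central airways, then the segmental
#: groups of the five lobes.
AIRWAY_REGIONS: tuple[str, ...] = (
    "trachea",
    "RMB",
    "LMB",
    "BronInt",
    "TriLLB",
    "sLUL",
    "sRUL",
    "sRML",
    "sLLL",
    "sRLL",
)

CENTRAL_REGIONS = AIRWAY_REGIONS[:5]
SEGMENTAL_REGIONS = AIRWAY_REGIONS[5:]


def circularity(area: float, perimeter: float) -> float:
    """Lumen circularity Cr = 4 pi A / P^2.

    Requires A > 0, P > 0 and the isoperimetric inequality P^2 >= 4 pi A
    (violations indicate inconsistent area/perimeter measurements).
    """
    area = float(area)
    perimeter = float(perimeter)
    if area <= 0 or perimeter <= 0:
        raise ValueError(f"area and perimeter must be positive, got A={area}, P={perimeter}")
    cr = 4.0 * math.pi * area / perimeter**2
    if cr > 1.0 + 1e-9:
        raise ValueError(
            f"isoperimetric inequality violated (4*pi*A/P^2 = {cr:.6f} > 1): "
            "inconsistent lumen area/perimeter"
        )
    return min(cr, 1.0)


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """Hydraulic diameter Dh = 4 A / P in mm (equals the diameter for a circle)."""
    area = float(area)
    perimeter = float(perimeter)
    if area <= 0 or perimeter <= 0:
        raise ValueError(f"area and perimeter must be positive, got A={area}, P={perimeter}")
    return 4.0 * area / perimeter


def normalize(value: float, predicted_tracheal: float) -> float:
    """Starred value: measurement divided by the healthy-predicted tracheal value."""
    if predicted_tracheal <= 0:
        raise ValueError(f"predicted tracheal value must be positive, got {predicted_tracheal}")
    return float(value) / float(predicted_tracheal)


@dataclass
class TracheaReferenceModel:
    """OLS predictor of a tracheal quantity from sex, age and height.

    ``coefficients`` are [intercept, sex, age, height] with sex coded 1 for
    male and 0 for female, age in years, height in cm.  Fitted on healthy
    subjects only; used to normalise every subject's WT and Dh.
    """

    response: str
    coefficients: np.ndarray
    residual_sd: float
    n_subjects: int

    _COVARIATES = ("sex", "age", "height")

    def predict(self, demographics: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(demographics))] + [np.asarray(demographics[c], float) for c in self._COVARIATES]
        )
        pred = X @ self.coefficients
        if np.any(pred <= 0):
            raise ValueError(
                f"reference model for {self.response!r} predicts non-positive values; "
                "covariates outside the fitting hull"
            )
        return pred


def fit_trachea_reference(healthy: pd.DataFrame, response: str) -> TracheaReferenceModel:
    """Fit the healthy tracheal reference model by ordinary least squares.

    ``healthy`` must contain one row per healthy subject with columns
    ``sex`` (1 = male, 0 = female), ``age`` (years), ``height`` (cm) and the
    response column (tracheal Dh or WT in mm).
    """
    import statsmodels.api as sm

    required = ["sex", "age", "height", response]
    missing = [c for c in required if c not in healthy.columns]
    if missing:
        raise ValueError(f"healthy reference table lacks columns {missing}")
    df = healthy.dropna(subset=required)
    if len(df) < 4:
        raise ValueError(
            f"need >= 4 healthy subjects with complete covariates to fit 4 parameters, got {len(df)}"
        )
    X = np.column_stack([np.asarray(df[c], float) for c in ("sex", "age", "height")])
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        names = ["intercept", "sex", "age", "height"]
        # identify columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(Xd.shape[1])
            if np.linalg.matrix_rank(np.delete(Xd, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design: collinear covariates {collinear}")
    fit = sm.OLS(np.asarray(df[response], float), Xd).fit()
    resid_sd = float(np.sqrt(fit.scale))
    return TracheaReferenceModel(
        response=response,
        coefficients=np.asarray(fit.params, float),
        residual_sd=resid_sd,
        n_subjects=len(df),
    )


def branch_metrics(branches: pd.DataFrame) -> pd.DataFrame:
    """Append per-branch Cr and Dh columns to a branch table.

    Expects columns ``subject_id``, ``region``, ``lumen_area_mm2``,
    ``lumen_perimeter_mm``, ``wall_thickness_mm``.
    """
    unknown = set(branches["region"]) - set(AIRWAY_REGIONS)
    if unknown:
        raise ValueError(f"unknown airway region labels: {sorted(unknown)}")
    out = branches.copy()
    out["Cr"] = [
        circularity(a, p) for a, p in zip(out["lumen_area_mm2"], out["lumen_perimeter_mm"])
    ]
    out["Dh"] = [
        hydraulic_diameter(a, p) for a, p in zip(out["lumen_area_mm2"], out["lumen_perimeter_mm"])
    ]
    out["WT"] = np.asarray(out["wall_thickness_mm"], float)
    return out


def summarize_regions(
    branches: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    dh_reference: TracheaReferenceModel | None = None,
    wt_reference: TracheaReferenceModel | None = None,
) -> pd.DataFrame:
    """Per-subject per-region Cr, Dh, WT (and Dh*, WT* when references given).

    Region values are unweighted means over a subject's branches in that
    region.  Regions with no branch for a subject are *absent* from the
    output (flagged missing, never imputed as zero).  Returns a long table
    with columns ``subject_id, region, metric, value``.
    """
    per_branch = branch_metrics(branches)
    agg = (
        per_branch.groupby(["subject_id", "region"], sort=False)[["Cr", "Dh", "WT"]]
        .mean()
        .reset_index()
    )
    if dh_reference is not None or wt_reference is not None:
        if demographics is None:
            raise ValueError("demographics table required to apply a tracheal reference")
        demo = demographics.set_index("subject_id")
        demo_rows = demo.loc[agg["subject_id"]]
        if dh_reference is not None:
            agg["Dh_star"] = agg["Dh"].to_numpy() / dh_reference.predict(demo_rows)
        if wt_reference is not None:
            agg["WT_star"] = agg["WT"].to_numpy() / wt_reference.predict(demo_rows)
    long = agg.melt(
        id_vars=["subject_id", "region"], var_name="metric", value_name="value"
    )
    return long.sort_values(["subject_id", "region", "metric"]).reset_index(drop=True)


def missing_regions(branches: pd.DataFrame) -> pd.DataFrame:
    """Subject x region pairs with no branch record (contract: flagged, not zeroed)."""
    subjects = branches["subject_id"].unique()
    have = set(zip(branches["subject_id"], branches["region"]))
    rows = [
        {"subject_id": s, "region": r}
        for s in subjects
        for r in AIRWAY_REGIONS
        if (s, r) not in have
    ]
    return pd.DataFrame(rows, columns=["subject_id", "region"])
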