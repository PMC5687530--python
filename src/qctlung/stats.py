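"""Three-group nonparametric comparison with family-wise FDR control.

The comparison design mirrors a healthy / asthma / COPD contrast: per
variable x region, a Kruskal-Wallis omnibus test plus the three pairwise
rank-sum contrasts (healthy-asthma, asthma-COPD, COPD-healthy), with
Benjamini-Hochberg step-up control of the false discovery rate applied once
across the whole emitted family of tests (q = 0.01 by default).  Categorical
variables are compared with Pearson's chi-square (no continuity correction).

Pairwise significance is annotated with the conventional footnote symbols:
``*`` healthy vs asthma, ``†`` asthma vs COPD, ``‡`` COPD vs healthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUPS: tuple[str, ...] = ("healthy", "asthma", "COPD")
PAIRS: tuple[tuple[str, str], ...] = (("healthy", "asthma"), ("asthma", "COPD"), ("COPD", "healthy"))
PAIR_SYMBOLS: dict[tuple[str, str], str] = {
    ("healthy", "asthma"): "*",
    ("asthma", "COPD"): "†",   # dagger
    ("COPD", "healthy"): "‡",  # double dagger
}


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-rank tie correction) and chi-square p, df = k-1.

    All-identical pooled data is degenerate (no rank separation possible) and
    returns (0.0, 1.0) rather than failing.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("each group needs at least one observation")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, df = (r-1)(c-1), no
    continuity correction."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("contingency table must hold non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bh_adjust(p_values: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: reject all i <= max{i : p(i) <= i q / m}.

    Returns (reject, p_adjusted); adjusted values are monotone non-decreasing
    in the raw p-values.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class ComparisonResult:
    """One test of the family: omnibus or a pairwise contrast."""

    variable: str
    region: str
    test: str                      # "kruskal_wallis" | "pairwise_rank" | "chi_square"
    contrast: str                  # "omnibus" or "groupA_vs_groupB"
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    reject: bool = False
    symbol: str = ""
    group_summary: dict = field(default_factory=dict)


def _group_summary(samples: dict[str, np.ndarray]) -> dict:
    out = {}
    for g, x in samples.items():
        n = len(x)
        mean = float(np.mean(x))
        # 95% normal-approximation CI half-width, as in mean (+/- CI) reporting
        half = float(1.96 * np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        out[g] = {"n": n, "mean": mean, "ci95_half_width": half}
    return out


def compare_groups(
    metrics: pd.DataFrame,
    family_q: float = 0.01,
    include_pairwise: bool = True,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Run the full three-group comparison family on a long metric table.

    ``metrics`` columns: ``subject_id, group, metric, region, value``.  Per
    metric x region, a Kruskal-Wallis omnibus test and (optionally) the three
    pairwise rank contrasts; BH is applied once across every emitted p-value.
    Variables observed in fewer than two groups are skipped with a log entry.

    Returns a tidy results table; the ``symbol`` column carries the
    * / † / ‡ pairwise-significance annotation.
    """
    required = {"group", "metric", "region", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")
    results: list[ComparisonResult] = []
    log = log if log is not None else []
    for (var, region), block in metrics.groupby(["metric", "region"], sort=False):
        samples = {
            g: sub["value"].to_numpy(dtype=float)
            for g, sub in block.groupby("group", sort=False)
        }
        samples = {g: x[np.isfinite(x)] for g, x in samples.items()}
        samples = {g: x for g, x in samples.items() if len(x) > 0}
        if len(samples) < 2:
            log.append(f"skipped {var}/{region}: fewer than two groups with data")
            continue
        ordered = [samples[g] for g in GROUPS if g in samples]
        h, p = kruskal_wallis(ordered)
        results.append(
            ComparisonResult(var, region, "kruskal_wallis", "omnibus", h, p,
                             group_summary=_group_summary(samples))
        )
        if include_pairwise:
            for a, b in PAIRS:
                if a not in samples or b not in samples:
                    continue
                u, pp = sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
                r = ComparisonResult(var, region, "pairwise_rank", f"{a}_vs_{b}",
                                     float(u), float(pp))
                r.symbol = PAIR_SYMBOLS[(a, b)]
                results.append(r)
    if not results:
        raise ValueError("no testable variable/region combinations in the metric table")
    praw = np.array([r.p_raw for r in results])
    reject, padj = bh_adjust(praw, q=family_q)
    for r, rej, pa in zip(results, reject, padj):
        r.reject = bool(rej)
        r.p_adjusted = float(pa)
        if not r.reject:
            r.symbol = ""
    log.append(f"BH family size: {len(results)} tests at q={family_q}")
    rows = [
        {
            "metric": r.variable,
            "region": r.region,
            "test": r.test,
            "contrast": r.contrast,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "reject": r.reject,
            "symbol": r.symbol,
            "group_summary": r.group_summary,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def simulate_null_fdr(
    n_cohorts: int = 500,
    n_tests: int = 87,
    group_sizes: dict[str, int] | int = 50,
    q: float = 0.01,
    seed: int = 0,
) -> dict:
    """Estimate the empirical FDR of the BH-controlled comparison family
    under the global null.

    Each cohort draws three exchangeable groups for ``n_tests`` independent
    variables, runs the omnibus family through :func:`compare_groups` and
    applies BH at ``q``.  Under the global null every rejection is false, so
    a cohort's false-discovery proportion is 1 whenever it rejects anything;
    the estimator is the mean over cohorts, reported with a 95% binomial
    (normal-approximation) confidence interval.
    """
    from .phantom import null_family_config, generate_cohort_metrics

    hits = 0
    for c in range(n_cohorts):
        cfg = null_family_config(n_tests=n_tests, n_per_group=group_sizes,
                                 seed=(int(seed) * 1_000_003 + c) % (2**31))
        metrics = generate_cohort_metrics(cfg)
        results = compare_groups(metrics, family_q=q, include_pairwise=False)
        if int(results["reject"].sum()) > 0:
            hits += 1
    fdr = hits / n_cohorts
    half = 1.96 * np.sqrt(max(fdr * (1 - fdr), 1.0 / n_cohorts) / n_cohorts)
    return {
        "fdr": fdr,
        "n_cohorts": n_cohorts,
        "n_tests": n_tests,
        "ci95": (max(fdr - half, 0.0), min(fdr + half, 1.0)),
        "q": q,
    }


def format_report(results: pd.DataFrame, q: float = 0.01) -> str:
    """Markdown report mirroring the mean (±CI) + footnote-symbol convention."""
    lines = [
        "# Group comparison report",
        "",
        f"BH-controlled family of {len(results)} tests at q = {q}.",
        "Symbols: * healthy vs asthma, † asthma vs COPD, ‡ COPD vs healthy (P < q after BH).",
        "",
        "| metric | region | symbols | group means (±95% CI) |",
        "|---|---|---|---|",
    ]
    for (metric, region), block in results.groupby(["metric", "region"], sort=False):
        syms = "".join(sorted(set("".join(block["symbol"]))))
        omni = block[block["contrast"] == "omnibus"]
        summary = ""
        if len(omni):
            gs = omni.iloc[0]["group_summary"]
            summary = "; ".join(
                f"{g}: {d['mean']:.3g} (±{d['ci95_half_width']:.2g})" for g, d in gs.items()
            )
        lines.append(f"| {metric} | {region} | {syms or '—'} | {summary} |")
    return "\n".join(lines) + "\n"
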