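"""Three-group comparison with family-wide FDR control.

Generates a 50-per-group cohort with the default disease pattern, runs the
Kruskal-Wallis + pairwise rank family with Benjamini-Hochberg control at
q = 0.01 and prints which asthma-vs-COPD contrasts survive — the parenchymal
density metrics should, the airway metrics mostly should not (the two
disease groups are configured to narrow similarly).
"""

from qctlung import CohortConfig, compare_groups, generate_cohort_metrics

cohort = generate_cohort_metrics(CohortConfig(n_per_group=50, seed=4))
log: list[str] = []
results = compare_groups(cohort, family_q=0.01, log=log)

print(log[-1])
print(f"total rejections: {int(results['reject'].sum())} of {len(results)} tests")

dagger = results[(results["contrast"] == "asthma_vs_COPD") & results["reject"]]
by_metric = dagger.groupby("metric")["region"].apply(list)
print("\nasthma-vs-COPD contrasts significant after BH (the † family):")
for metric, regions in by_metric.items():
    print(f"  {metric:12s} {', '.join(regions)}")
print("\nEmph%, fSAD%, beta_tissue and Jacobian separate the two diseases;")
print("airway calibre (Dh*) does not, matching the configured pattern.")
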