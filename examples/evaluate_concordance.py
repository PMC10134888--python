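"""Per-KO Spearman concordance of observed vs predicted KO abundances.

Restricts all tables to the KOs present in every dataset, computes KO-specific
Spearman correlations overall and within each community cluster, and contrasts
them with a 20-replicate permutation null in which each KO column is shuffled
across samples independently in both tables.
"""

from mginfeval import (
    GeneratorConfig,
    PermutationPlan,
    feature_concordance,
    generate_paired_dataset,
    permutation_robustness,
    restrict_to_shared_features,
    summarize_concordance,
)

dataset = generate_paired_dataset(GeneratorConfig(seed=7))
observed, predicted, shared = restrict_to_shared_features(
    dataset.observed_ko, dataset.predicted_ko
)
print(f"shared KOs: {shared.n_shared} (per source: {dict(shared.source_counts)})")

records = feature_concordance(observed, predicted, dataset.frame)
summary = summarize_concordance(records)
cluster_rows = summary[summary["stratum_type"].isin(["overall", "cluster"])]
print(cluster_rows[["stratum", "method", "median_rho", "min_rho", "max_rho"]]
      .round(3).to_string(index=False))

plan = PermutationPlan(n_permutations=20, seed=1)
_, null = permutation_robustness(
    observed, predicted, plan,
    evaluator=lambda o, p: feature_concordance(o, p, dataset.frame, ("overall",)),
    summarizer=summarize_concordance,
)
print("\npermutation null (grand median of per-replicate median rho):")
print(null.round(4).to_string(index=False))

# Real concordance is clearly positive and highest in the crispatus-dominated
# cluster; under permutation it collapses to ~0, so the statistic genuinely
# tracks the pairing of observed and predicted samples.
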