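"""Concordance of signed log10 P values between observed and predicted data.

For every KO a two-sided Wilcoxon rank-sum test compares cases vs controls,
separately on observed and predicted tables; P values are folded into
Pt = log10(P) x sign(mean_case - mean_control), and the Spearman correlation
between the observed and predicted Pt vectors measures whether inference
would lead to the same differential-abundance conclusions.
"""

from mginfeval import (
    GeneratorConfig,
    generate_paired_dataset,
    pvalue_concordance,
    restrict_to_shared_features,
    summarize_pconcordance,
)

dataset = generate_paired_dataset(GeneratorConfig(seed=7))
observed, predicted, _ = restrict_to_shared_features(
    dataset.observed_ko, dataset.predicted_ko
)
pt_records, concordance = pvalue_concordance(
    observed, predicted, dataset.frame, annotation=dataset.annotation
)
out = summarize_pconcordance(concordance)
print(out[out["stratum_type"] != "category"][["stratum", "method", "rho"]]
      .round(3).to_string(index=False))
print()
print("by functional category (overall samples, KOs grouped):")
print(out[out["stratum_type"] == "category"][["stratum", "method", "rho"]]
      .round(3).to_string(index=False))

# Pt concordance is highest in the crispatus-dominated cluster and collapses
# in the iners-dominated cluster, where the discard-mode prediction loses the
# dominant taxon: the case/control signal survives inference only where the
# reference represents the community well.
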