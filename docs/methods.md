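# Methods

This note documents the models and procedures implemented in `mginfeval`, the
defaults and why they were chosen, and what conclusions the synthetic
experiments do and do not support.

## Evaluation statistics

**Abundance concordance.** All tables are first restricted to the KOs with
relative abundance > 0 in at least one sample of the observed table *and* of
every predicted table (the "shared" set). Values are **not** renormalized
after restriction — correlations are computed on the relative abundances as
produced; a `renormalize=True` flag gives the alternative, since published
analyses are often ambiguous on this point. For each KO, Spearman's ρ
(mid-ranks for ties, Pearson on ranks) is computed between observed and
predicted values across the samples of a stratum: overall, each community
cluster, and — reusing the overall records — each level-1 functional
category (categories partition KOs, not samples). Correlations of constant
vectors are reported as *undefined* with a reason and excluded from medians,
never coerced to 0; strata with fewer than 3 samples are likewise flagged.
Cluster labels are an explicit input: the evaluator never clusters
internally, so taxonomic clustering and functional evaluation stay decoupled.

**Signed log-P concordance.** For each KO a two-sided Wilcoxon rank-sum test
compares case vs control relative abundances, separately on observed and on
each predicted table, using only the stratum's samples. P values are folded
into a single signed quantity

    Pt = log10(P) × sign(mean_case − mean_control)

and one Spearman ρ between the observed-data and predicted-data Pt vectors is
reported per stratum. Numerical conventions: P is floored at 1e-300 before
the log so Pt is always finite; an exact mean tie gives sign 0 and Pt = 0;
Pt is odd under swapping the groups. The Wilcoxon switches between an exact
null (both groups ≤ 10: closed-form when tie-free, mid-rank-sum enumeration
when tied, both using the two-sided rule 2·min(P≤, P≥) capped at 1) and the
normal approximation with tie and continuity corrections. No multiple-testing
correction is applied anywhere — raw P values enter Pt by construction.

**Permutation robustness check.** Each KO column is permuted across samples
independently, separately in the observed and every predicted table, and the
full evaluation re-runs on each of (default) 100 replicates. The permutation
for (table, replicate, KO) is its own deterministic child stream of the plan
seed, so the two tables' permutations are mutually independent and any
replicate can be replayed in isolation. The unpermuted evaluation is never
part of the null. Every column's multiset of values is preserved exactly.

## Community structure

Sample-to-sample distance is the Jensen–Shannon divergence in natural-log
units, used directly (no square root): JSD ∈ [0, ln 2], symmetric, zero iff
equal. Agglomeration uses the Ward.D2 criterion on the supplied distances
(squared-distance Lance–Williams update), matching `hclust(method="ward.D2")`
on a JSD distance object; the scipy nearest-neighbor-chain implementation is
deterministic, and on continuous compositional data exactly tied merge
candidates have probability zero. Cutting at k is by the standard maxclust
rule with labels renumbered in order of first appearance.

Internal validation statistics per candidate k: connectivity
(Σᵢ Σⱼ₌₁..L (1/j)·[j-th nearest neighbor of i not co-clustered], L = 10 by
default, neighbor ties broken by sample order), mean silhouette width on the
precomputed distances, and the Dunn index (minimum between-cluster distance /
maximum within-cluster diameter). The optimum per statistic is *reported*,
never acted on: the cluster count is always a user decision, because internal
statistics can prefer merging biologically distinct community types (in the
reference setting, iners-dominated with mixed).

Alpha diversity supports observed richness (count of features > 0), Shannon
(−Σ p ln p), Simpson (1 − Σ p²) and inverse Simpson (1/Σ p²); evenness
metrics convert counts to proportions internally, and richness on relative
data uses presence > 0.

## The synthetic generator

The generator produces a `PairedDataset` — taxon table, observed KO table,
predicted KO tables, sample metadata, KO annotation, and the full generating
truth — from one config whose defaults are the reference study design.

**Community structure.** 72 samples: 17 *L. crispatus*-dominated (11 cases),
31 *L. iners*-dominated (13 cases), 24 mixed (11 cases); case/control labels
are assigned by seeded permutation within cluster. Eight taxa by default: the
two lactobacilli, a Gardnerella-like taxon, four other anaerobes and
*L. jensenii*. Dominated clusters use a two-level composition model: the
dominant-taxon fraction is Beta(c·m, c·(1−m)) with dominance mean m (0.87
crispatus, 0.86 iners) and concentration c (default 15, giving a dominance
standard deviation ≈ 0.085, the realistic spread of community-state-type
dominance), while the remaining mass is spread over the minor taxa by a
Dirichlet centred on a fixed minor profile at concentration 150 (stable
relative minor composition). A single-concentration Dirichlet was rejected
because it ties the two spreads together: with a realistic dominant-fraction
spread the minor proportions become wildly variable (per-taxon α < 1), and
that shared minor-taxon variation keeps observed and error-degraded predicted
tables spuriously concordant, masking the differential-error mechanism the
generator exists to produce. The mixed cluster is a plain Dirichlet
(concentration 40) on its template. Cluster mean compositions equal the
templates exactly, and infinite concentration collapses samples onto them.

**Genome content.** KOs (default 500) are partitioned across six level-1
functional categories at fixed proportions (metabolism 40%, genetic
information processing 15%, BRITE hierarchies 15%, environmental information
processing / cellular processes / uncharacterized 10% each). Each taxon's
genome row allocates mass to categories per its category-weight profile —
the iners-like taxon is enriched for genetic information processing (0.32 vs
0.10 for crispatus) and depleted for uncharacterized genes (0.05 vs 0.20),
the documented genomic contrast between the species — then spreads each
category's mass over its KOs by a flat Dirichlet. Rows are strictly
stochastic (sum to 1).

**Observed table.** Sample KO vector = composition × genome content,
multiplied elementwise by log-normal noise (default σ = 0.2 on the log scale,
moderate measurement noise for shotgun-derived relative abundances), then
renormalized.

**Case/control signal.** By default cases carry a taxonomic effect: their
*L. crispatus* abundance is scaled by 0.3 before renormalization, encoding
the protective crispatus–term-birth association and giving the cohort a
genuine composition–outcome signal for the differential evaluation to
recover; because the shift is taxonomic, predictions inherit it through the
taxon table wherever the reference represents the taxon. KO-level effects
(`effect_kos`) are instead applied only to the observed table — functional
signal invisible to taxonomy — and default to none, so the
perfect-prediction identity (zero noise, perfect reference ⇒ observed =
predicted) holds under defaults.

**Reference-fidelity model.** Each taxon has an ANI-like similarity to its
nearest reference (defaults: crispatus 0.995, jensenii 0.98, Prevotella 0.97,
Gardnerella/Megasphaera 0.96, Atopobium 0.95, Sneathia 0.94, iners 0.92).
Two error modes:

- `discard_renormalize` (Tax4Fun2-like): taxa with ANI < 0.97 are dropped,
  the remainder renormalized, then multiplied by the true genome rows; the
  per-sample discarded-abundance fraction is reported. A sample losing its
  entire composition is an error naming the sample.
- `retain_blend` (PICRUSt2-like): every taxon is kept, but its genome row is
  blended with a fixed, seeded log-normal perturbation of itself
  (σ = 1.0); the weight on the true row is ANI^25, so fidelity decays fast
  below ANI ≈ 0.99.

Under the defaults the discard mode removes ~90% of abundance in
iners-dominated samples and ~10% in crispatus-dominated ones — the
differential reference gap that makes inference error cluster-dependent.

**Reproducibility.** All randomness flows from the single config seed through
named child streams (`genome`, `taxa`, `noise`, `predict/<label>`, and per
(table, replicate, KO) for permutations), so identical configs produce
byte-identical outputs and any stage can be replayed alone.

## What the generator does and does not emulate

It reproduces the *statistical structure* of the problem: community state
types with realistic dominance spread, genome-content coupling of taxa to
functional categories, differential reference fidelity, and a case-control
design with a taxonomic outcome signal. It does **not** emulate: sequencing
reads or their processing; amplification/copy-number bias; real KEGG content
(categories and KO weights are stylized); strain-level variation within taxa;
compositional count noise (values are continuous proportions); or the actual
PICRUSt2/Tax4Fun2 algorithms (their failure *mechanisms* are abstracted into
the two error modes). Passing tests therefore show that the evaluation
statistics behave correctly *given* differential reference error — they do
not certify any particular tool's accuracy on real data, and observed
concordance magnitudes here need not match real-data values.

## Numerical and interface choices

- TSV (UTF-8, tab, '.' decimal) is the only dialect; features and samples
  match by identifier, never position. Relative tables must row-sum to 1
  within 1e-9 (reading renormalizes away round-trip error before checking).
- Each KO carries exactly one level-1 category; resolving multi-category KOs
  is upstream annotation's responsibility.
- Shared-KO restriction: a KO qualifies in a dataset if its abundance exceeds
  0 in at least one sample of that dataset.
- Spearman of constant vectors, strata under 3 samples, and strata missing
  cases or controls are all flagged, never silently dropped or zeroed.
- The crispatus/iners ratio predictor uses (num + ε)/(den + ε) with ε = 1e-6
  (configurable) against zero denominators; regressions are plain
  untransformed least squares, R² = 1 − SSE/SST, with constant responses
  giving R² = 0 by convention and constant predictors an error.
- Pipeline runs write a manifest of every resolved parameter; equal manifests
  produce byte-identical outputs.

## Problem sizes

Simulation-backed checks run at the study's own design scale — 72 samples,
500 KOs — with 100 permutation replicates for the nulls and 20 independent
seeds for the ordering and calibration properties; the 1,000-sample
calibration check enlarges only the cluster sizes. These sizes make every
distributional claim in the test suite a direct computation, not an
extrapolation.

## Known limitations

- The exact tie-aware Wilcoxon enumerates rank-sum assignments and is
  intended for group sizes ≤ 10; larger tied groups use the corrected normal
  approximation, as standard.
- Connectivity's neighbor ranking breaks distance ties by sample order;
  against tied distances the statistic therefore depends on input order
  (documented, deterministic).
- `fcluster`-style cutting can fail to produce exactly k clusters when merge
  heights tie exactly; the cut then raises rather than silently returning a
  different k.
- The generator's minor-taxon profiles, category proportions and ANI defaults
  are stylized calibration choices (the underlying study reports means, not
  variances); they are exposed in the config and recorded in every run's
  truth metadata.
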