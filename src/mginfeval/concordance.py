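"""Evaluation approach 1: per-KO Spearman concordance of observed vs predicted
relative abundances, with stratification and a permutation robustness check.

All tables are first restricted to the KOs present (relative abundance > 0 in
at least one sample) in the observed table and in every predicted table; values
are *not* renormalized after restriction (a flag exposes the alternative).
Per-KO Spearman correlations are then computed overall, within each community
cluster, and grouped by functional category.  The robustness check permutes
each KO's values across samples independently in the observed and predicted
tables and re-runs the evaluation: a trustworthy concordance statistic should
collapse to ~0 under this null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from ._rng import child_rng
from .tables import AbundanceTable, FeatureAnnotation, SampleFrame, TableError

__all__ = [
    "SharedFeatureSet",
    "PermutationPlan",
    "restrict_to_shared_features",
    "spearman",
    "columnwise_spearman",
    "feature_concordance",
    "summarize_concordance",
    "permute_pair",
    "permutation_robustness",
]

STRATUM_OVERALL = "overall"


@dataclass(frozen=True)
class SharedFeatureSet:
    """KOs positive in every dataset, plus each source's original counts."""

    feature_ids: tuple[str, ...]
    source_counts: Mapping[str, int]

    @property
    def n_shared(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class PermutationPlan:
    """Permutation-null specification: replicate count and master seed.

    Each (table, replicate, KO) triple gets its own child RNG stream, so the
    observed and predicted tables — and every KO within them — are permuted
    independently, and any replicate can be replayed in isolation.
    """

    n_permutations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _positive_features(table: AbundanceTable) -> pd.Index:
    return table.data.columns[(table.data > 0).any(axis=0)]


def restrict_to_shared_features(
    observed: AbundanceTable,
    predicted: Mapping[str, AbundanceTable],
    renormalize: bool = False,
) -> tuple[AbundanceTable, dict[str, AbundanceTable], SharedFeatureSet]:
    """Restrict all tables to KOs positive in every dataset.

    Feature order follows the observed table.  By default the retained values
    are kept exactly as produced; ``renormalize=True`` rescales rows to sum to
    1 after restriction instead.
    """
    for label, table in predicted.items():
        if table.sample_ids != observed.sample_ids:
            raise TableError(f"predicted table {label!r} is not sample-aligned")
    pos_obs = _positive_features(observed)
    shared = set(pos_obs)
    counts = {"observed": len(pos_obs)}
    for label, table in predicted.items():
        pos = _positive_features(table)
        counts[label] = len(pos)
        shared &= set(pos)
    if not shared:
        raise TableError("no features shared across observed and predicted tables")
    order = [f for f in pos_obs if f in shared]

    def _cut(table: AbundanceTable) -> AbundanceTable:
        df = table.data.loc[:, order]
        if renormalize:
            df = df.div(df.sum(axis=1), axis=0)
            return AbundanceTable(df, "relative")
        # rows no longer sum to 1 after restriction, so the scale tag falls
        # back to "counts" (unnormalized non-negative values)
        return AbundanceTable(df, "counts")
    obs_cut = _cut(observed)
    pred_cut = {label: _cut(t) for label, t in predicted.items()}
    return obs_cut, pred_cut, SharedFeatureSet(tuple(order), counts)


def spearman(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation (mid-ranks for ties); None if undefined.

    Undefined when either vector is constant, in which case the rank variance
    is zero and no correlation exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(spearmanr(x, y).statistic)


def columnwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column Spearman rho between two aligned matrices; NaN if undefined.

    Equivalent to calling :func:`spearman` on each column pair, but vectorized
    (mid-ranks per column, then a column-wise Pearson correlation of ranks).
    """
    rx = rankdata(x, axis=0)
    ry = rankdata(y, axis=0)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx**2).sum(axis=0))
    sy = np.sqrt((ry**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry).sum(axis=0) / (sx * sy)
    rho[(sx == 0) | (sy == 0)] = np.nan
    return rho


def _strata(frame: SampleFrame, strata: Sequence[str]) -> dict[str, list[str]]:
    """Map stratum label → sample ids.  'overall' plus one per cluster label."""
    out: dict[str, list[str]] = {}
    for s in strata:
        if s == STRATUM_OVERALL:
            out[STRATUM_OVERALL] = frame.sample_ids
        elif s == "cluster":
            clusters = frame.cluster.dropna()
            for label in pd.unique(clusters):
                out[str(label)] = list(clusters.index[clusters == label])
        else:
            raise ValueError(f"unknown stratum specification {s!r}")
    return out


def feature_concordance(
    observed: AbundanceTable,
    predicted: Mapping[str, AbundanceTable],
    frame: SampleFrame,
    strata: Sequence[str] = (STRATUM_OVERALL, "cluster"),
    annotation: FeatureAnnotation | None = None,
) -> pd.DataFrame:
    """Per-KO Spearman rho between observed and each predicted table.

    Returns a tidy frame with columns ``feature_id, stratum, stratum_type,
    method, rho, n_samples, reason``.  Sample strata are 'overall' and each
    cluster; when an annotation is given, the overall records are additionally
    re-labelled by functional category (KO grouping varies, the sample set
    does not).  Undefined correlations (constant vectors, strata with < 3
    samples) are flagged with a reason, never silently dropped.
    """
    sample_strata = _strata(frame, strata)
    features = observed.feature_ids
    records = []
    for method, pred in predicted.items():
        if pred.sample_ids != observed.sample_ids or pred.feature_ids != features:
            raise TableError(f"predicted table {method!r} is not aligned")
        for stratum, ids in sample_strata.items():
            stype = "overall" if stratum == STRATUM_OVERALL else "cluster"
            n = len(ids)
            if n < 3:
                for f in features:
                    records.append(
                        (f, stratum, stype, method, np.nan, n, "fewer than 3 samples")
                    )
                continue
            x = observed.data.loc[ids].to_numpy()
            y = pred.data.loc[ids].to_numpy()
            rho = columnwise_spearman(x, y)
            for f, r in zip(features, rho):
                reason = "constant vector" if np.isnan(r) else ""
                records.append((f, stratum, stype, method, r, n, reason))
    df = pd.DataFrame(
        records,
        columns=["feature_id", "stratum", "stratum_type", "method", "rho",
                 "n_samples", "reason"],
    )
    if annotation is not None:
        overall = df[df["stratum"] == STRATUM_OVERALL].copy()
        cats = annotation.category_l1.reindex(overall["feature_id"]).to_numpy()
        overall["stratum"] = cats
        overall["stratum_type"] = "category"
        df = pd.concat([df, overall], ignore_index=True)
    return df


def summarize_concordance(records: pd.DataFrame) -> pd.DataFrame:
    """Median/min/max rho per (stratum, method), with undefined counts."""
    if records.empty:
        raise ValueError("no concordance records to summarize")
    rows = []
    for (stratum, stype, method), grp in records.groupby(
        ["stratum", "stratum_type", "method"], sort=False
    ):
        defined = grp["rho"].dropna()
        rows.append(
            {
                "stratum": stratum,
                "stratum_type": stype,
                "method": method,
                "median_rho": defined.median() if len(defined) else np.nan,
                "min_rho": defined.min() if len(defined) else np.nan,
                "max_rho": defined.max() if len(defined) else np.nan,
                "n_defined": int(len(defined)),
                "n_undefined": int(grp["rho"].isna().sum()),
            }
        )
    return pd.DataFrame(rows)


def permute_pair(
    observed: AbundanceTable,
    predicted: Mapping[str, AbundanceTable],
    plan: PermutationPlan,
    replicate: int,
) -> tuple[AbundanceTable, dict[str, AbundanceTable]]:
    """Independently permute each KO column across samples in every table.

    Each column's multiset of values is preserved exactly; the permutation for
    table t, replicate r, KO j is the deterministic child stream
    (plan.seed, t, r, j), so observed and predicted permutations are mutually
    independent and fully replayable.
    """
    if not 0 <= replicate < plan.n_permutations:
        raise ValueError(f"replicate {replicate} outside [0, {plan.n_permutations})")

    def _permute(table: AbundanceTable, token: str) -> AbundanceTable:
        values = table.data.to_numpy().copy()
        n = values.shape[0]
        for j in range(values.shape[1]):
            perm = child_rng(plan.seed, token, replicate, j).permutation(n)
            values[:, j] = values[perm, j]
        df = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
        return AbundanceTable(df, table.scale)

    obs_perm = _permute(observed, "observed")
    pred_perm = {label: _permute(t, f"predicted:{label}") for label, t in predicted.items()}
    return obs_perm, pred_perm


def permutation_robustness(
    observed: AbundanceTable,
    predicted: Mapping[str, AbundanceTable],
    plan: PermutationPlan,
    evaluator: Callable[
        [AbundanceTable, Mapping[str, AbundanceTable]], pd.DataFrame
    ],
    summarizer: Callable[[pd.DataFrame], pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``evaluator`` on every permuted replicate and pool the summaries.

    The unpermuted evaluation is never part of the null.  Returns the
    per-replicate summary table (with a ``replicate`` column) and its grand
    summary (median / 2.5% / 97.5% quantiles of each stratum's statistic
    across replicates).
    """
    per_replicate = []
    for r in range(plan.n_permutations):
        obs_p, pred_p = permute_pair(observed, predicted, plan, r)
        summary = summarizer(evaluator(obs_p, pred_p))
        summary.insert(0, "replicate", r)
        per_replicate.append(summary)
    all_reps = pd.concat(per_replicate, ignore_index=True)
    stat_col = "median_rho" if "median_rho" in all_reps.columns else "rho"
    grand = (
        all_reps.groupby(["stratum", "method"], sort=False)[stat_col]
        .agg(
            grand_median="median",
            q025=lambda s: s.quantile(0.025),
            q975=lambda s: s.quantile(0.975),
        )
        .reset_index()
    )
    return all_reps, grand
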