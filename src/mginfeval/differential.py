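"""Evaluation approach 2: concordance of signed log10 P values.

For every KO, a two-sided Wilcoxon rank-sum test compares case vs control
relative abundances, separately in the observed and in each predicted table,
and the P value is folded into a single signed quantity

    Pt = log10(P) × sign(mean_case − mean_control),

so that small P with higher abundance in cases maps to a large negative value,
small P with higher abundance in controls to a large positive value, and
P = 1 (or an exact mean tie) to 0.  The Spearman correlation between the
observed-data and predicted-data Pt vectors across KOs measures whether an
inferred metagenome would have led to the same differential-abundance
conclusions as the observed one.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .concordance import STRATUM_OVERALL, columnwise_spearman, spearman
from .tables import AbundanceTable, FeatureAnnotation, SampleFrame, TableError

__all__ = [
    "wilcoxon_rank_sum",
    "transform_p",
    "pvalue_concordance",
    "summarize_pconcordance",
    "P_FLOOR",
]

# the transform is undefined at P = 0; floor well above double underflow
P_FLOOR = 1e-300

_EXACT_MAX = 10  # per-group size at or below which the exact null is used


def _exact_tied_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum P by mid-rank enumeration (handles ties).

    Enumerates every assignment of the pooled values to a group of size
    len(x), computes the mid-rank sum for each, and returns
    2·min(P(S ≤ s), P(S ≥ s)) capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    s_obs = ranks[:nx].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), nx)]
    )
    tol = 1e-9
    p_le = np.mean(sums <= s_obs + tol)
    p_ge = np.mean(sums >= s_obs - tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) P value.

    ``method="auto"`` (default) uses the exact null distribution when both
    groups have ≤ 10 observations (closed form when tie-free, mid-rank
    enumeration when tied) and the normal approximation with tie and
    continuity corrections otherwise; ``"exact"`` or ``"asymptotic"`` force
    one branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size < 3:
        raise ValueError("need at least 3 observations in total")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    small = x.size <= _EXACT_MAX and y.size <= _EXACT_MAX
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = small if method == "auto" else method == "exact"
    if exact and has_ties:
        return _exact_tied_p(x, y)
    return float(
        mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        ).pvalue
    )


def transform_p(p: float, mean_case: float, mean_control: float) -> float:
    """Signed log10 P: Pt = log10(P) × sign(mean_case − mean_control).

    P must lie in (0, 1]; it is floored at 1e-300 before the log so the
    transform is always finite.  An exact mean tie yields Pt = 0.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"P value must lie in (0, 1], got {p}")
    sign = float(np.sign(mean_case - mean_control))
    return float(np.log10(max(p, P_FLOOR)) * sign)


def _wilcoxon_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column two-sided rank-sum P for case matrix x vs control matrix y."""
    if x.shape[0] > _EXACT_MAX or y.shape[0] > _EXACT_MAX:
        # vectorized asymptotic path (tie and continuity corrected)
        return np.atleast_1d(
            mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic").pvalue
        )
    return np.array(
        [wilcoxon_rank_sum(x[:, j], y[:, j]) for j in range(x.shape[1])]
    )


def _pt_records(
    table: AbundanceTable,
    dataset: str,
    stratum: str,
    case_ids: list[str],
    control_ids: list[str],
) -> pd.DataFrame:
    xs = table.data.loc[case_ids].to_numpy()
    ys = table.data.loc[control_ids].to_numpy()
    pvals = np.clip(_wilcoxon_matrix(xs, ys), P_FLOOR, 1.0)
    mean_case = xs.mean(axis=0)
    mean_control = ys.mean(axis=0)
    sign = np.sign(mean_case - mean_control)
    pt = np.log10(pvals) * sign
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "dataset": dataset,
            "stratum": stratum,
            "p_value": pvals,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "sign": sign.astype(int),
            "pt": pt,
        }
    )


def pvalue_concordance(
    observed: AbundanceTable,
    predicted: Mapping[str, AbundanceTable],
    frame: SampleFrame,
    strata: Sequence[str] = (STRATUM_OVERALL, "cluster"),
    annotation: FeatureAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pt records per KO and Spearman Pt concordance per stratum.

    Sample strata ('overall', each cluster) re-test cases vs controls using
    only that stratum's samples; functional categories partition KOs, not
    samples, so category rows correlate subsets of the *overall* Pt vectors.
    Strata missing either cases or controls are skipped with a diagnostic row
    (rho = NaN) rather than silently dropped.
    """
    features = observed.feature_ids
    for label, pred in predicted.items():
        if pred.sample_ids != observed.sample_ids or pred.feature_ids != features:
            raise TableError(f"predicted table {label!r} is not aligned")

    sample_strata: dict[str, list[str]] = {}
    for s in strata:
        if s == STRATUM_OVERALL:
            sample_strata[STRATUM_OVERALL] = observed.sample_ids
        elif s == "cluster":
            clusters = frame.cluster.dropna()
            for label in pd.unique(clusters):
                sample_strata[str(label)] = list(clusters.index[clusters == label])
        else:
            raise ValueError(f"unknown stratum specification {s!r}")

    pt_frames: list[pd.DataFrame] = []
    conc_rows: list[dict] = []
    overall_obs: pd.DataFrame | None = None
    overall_pred: dict[str, pd.DataFrame] = {}

    for stratum, ids in sample_strata.items():
        stype = "overall" if stratum == STRATUM_OVERALL else "cluster"
        sub = frame.select_samples(ids)
        cases, controls = sub.case_ids(), sub.control_ids()
        if not cases or not controls:
            for method in predicted:
                conc_rows.append(
                    {
                        "stratum": stratum,
                        "stratum_type": stype,
                        "method": method,
                        "rho": np.nan,
                        "n_features": 0,
                        "reason": "stratum lacks cases or controls",
                    }
                )
            continue
        obs_pt = _pt_records(observed, "observed", stratum, cases, controls)
        pt_frames.append(obs_pt)
        if stratum == STRATUM_OVERALL:
            overall_obs = obs_pt
        for method, pred in predicted.items():
            pred_pt = _pt_records(pred, method, stratum, cases, controls)
            pt_frames.append(pred_pt)
            if stratum == STRATUM_OVERALL:
                overall_pred[method] = pred_pt
            rho = spearman(obs_pt["pt"].to_numpy(), pred_pt["pt"].to_numpy())
            conc_rows.append(
                {
                    "stratum": stratum,
                    "stratum_type": stype,
                    "method": method,
                    "rho": np.nan if rho is None else rho,
                    "n_features": len(features),
                    "reason": "constant Pt vector" if rho is None else "",
                }
            )

    if annotation is not None and overall_obs is not None:
        cats = annotation.category_l1.reindex(features)
        for cat in pd.unique(cats.dropna()):
            members = np.flatnonzero((cats == cat).to_numpy())
            for method, pred_pt in overall_pred.items():
                if len(members) < 3:
                    rho, reason = None, "fewer than 3 KOs in category"
                else:
                    rho = spearman(
                        overall_obs["pt"].to_numpy()[members],
                        pred_pt["pt"].to_numpy()[members],
                    )
                    reason = "constant Pt vector" if rho is None else ""
                conc_rows.append(
                    {
                        "stratum": str(cat),
                        "stratum_type": "category",
                        "method": method,
                        "rho": np.nan if rho is None else rho,
                        "n_features": len(members),
                        "reason": reason,
                    }
                )

    pt_records = (
        pd.concat(pt_frames, ignore_index=True) if pt_frames else pd.DataFrame()
    )
    return pt_records, pd.DataFrame(conc_rows)


def summarize_pconcordance(records: pd.DataFrame) -> pd.DataFrame:
    """Tabulate Pt-concordance rho per (stratum, method); flag undefined rows."""
    if records.empty:
        raise ValueError("no Pt concordance records to summarize")
    out = records.copy()
    out["defined"] = ~out["rho"].isna()
    return out[
        ["stratum", "stratum_type", "method", "rho", "n_features", "defined", "reason"]
    ]
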