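"""Coupling between community composition and functional-category abundance.

Dominant-taxon relative abundance (or the crispatus/iners ratio) is used as
the explanatory variable in a simple untransformed linear model with each
level-1 functional category's summed KO relative abundance as the response;
the model R² quantifies how much of the functional variation community
composition explains, and the slope sign gives the direction of the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .tables import AbundanceTable, FeatureAnnotation, TableError

__all__ = [
    "RegressionResult",
    "category_abundance",
    "ols_r2",
    "taxon_category_coupling",
    "RATIO_PREDICTOR",
]

RATIO_PREDICTOR = "ratio"


@dataclass(frozen=True)
class RegressionResult:
    response: str        # functional category
    predictor: str       # taxon label or ratio label
    r_squared: float
    slope_sign: int      # -1, 0, +1
    n_samples: int


def category_abundance(
    ko_table: AbundanceTable, annotation: FeatureAnnotation
) -> AbundanceTable:
    """Sum member-KO abundances per level-1 category; conserves row totals."""
    missing = [f for f in ko_table.feature_ids if f not in annotation.data.index]
    if missing:
        raise TableError(f"unannotated features: {missing[:10]}")
    cats = annotation.category_l1.reindex(ko_table.feature_ids)
    grouped = ko_table.data.T.groupby(cats.to_numpy()).sum().T
    return AbundanceTable(grouped, ko_table.scale)


def ols_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Simple least-squares R² and slope sign for y = a + bx.

    A constant response gives R² = 0 by convention; a constant predictor is an
    error (the fit is ill-posed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("predictor is constant across samples")
    if np.all(y == y[0]):
        return 0.0, 0
    fit = linregress(x, y)
    return float(fit.rvalue**2), int(np.sign(fit.slope))


def taxon_category_coupling(
    taxon_table: AbundanceTable,
    ko_table: AbundanceTable,
    annotation: FeatureAnnotation,
    predictors: Sequence[str],
    ratio_numerator: str = "L_crispatus",
    ratio_denominator: str = "L_iners",
    ratio_pseudocount: float = 1e-6,
) -> list[RegressionResult]:
    """Regress each category's abundance on each requested predictor.

    Predictors are taxon names (their relative abundance) or the literal
    ``"ratio"``: (numerator + ε) / (denominator + ε) with a pseudocount ε
    guarding zero denominators (default 1e-6, configurable).
    """
    if taxon_table.sample_ids != ko_table.sample_ids:
        raise TableError("taxon and KO tables are not sample-aligned")
    categories = category_abundance(ko_table, annotation)
    results = []
    for pred in predictors:
        if pred == RATIO_PREDICTOR:
            for t in (ratio_numerator, ratio_denominator):
                if t not in taxon_table.data.columns:
                    raise TableError(f"unknown taxon {t!r} for ratio predictor")
            x = (
                (taxon_table.data[ratio_numerator] + ratio_pseudocount)
                / (taxon_table.data[ratio_denominator] + ratio_pseudocount)
            ).to_numpy()
            label = f"{ratio_numerator}/{ratio_denominator}"
        else:
            if pred not in taxon_table.data.columns:
                raise TableError(f"unknown taxon {pred!r}")
            x = taxon_table.data[pred].to_numpy()
            label = pred
        for cat in categories.feature_ids:
            r2, sign = ols_r2(x, categories.data[cat].to_numpy())
            results.append(
                RegressionResult(
                    response=cat,
                    predictor=label,
                    r_squared=r2,
                    slope_sign=sign,
                    n_samples=len(x),
                )
            )
    return results
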