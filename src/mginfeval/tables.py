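"""Tabular containers and I/O for paired taxon / KO abundance data.

The exchange object throughout the package is the :class:`AbundanceTable`, a
validated samples × features matrix of non-negative values that is either raw
``counts`` or row-normalized ``relative`` abundances.  Sample metadata
(case/control outcome plus an optional community-cluster label) travels in a
:class:`SampleFrame`, and the KO → functional-category map in a
:class:`FeatureAnnotation`.

All files are plain UTF-8 TSV with a header row; features and samples are
matched by identifier, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleFrame",
    "FeatureAnnotation",
    "TableError",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_feature_annotation",
    "write_feature_annotation",
    "normalize_relative",
    "align_samples",
]

_REL_TOL = 1e-9
_INFER_TOL = 1e-6

OUTCOME_CASE = "case"
OUTCOME_CONTROL = "control"


class TableError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_unique(ids: pd.Index, kind: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise TableError(f"duplicate {kind} identifiers: {dupes[:5]}")


@dataclass(frozen=True)
class AbundanceTable:
    """Samples × features abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and feature identifiers
        as columns; every cell is a finite non-negative number.
    scale
        ``"counts"`` or ``"relative"``.  Relative tables must have every row
        summing to 1 within 1e-9.
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "relative"):
            raise TableError(f"unknown scale {self.scale!r}")
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "feature")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise TableError(
                f"non-finite value at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative value {values[i, j]} at sample {df.index[i]!r}, "
                f"feature {df.columns[j]!r}"
            )
        if self.scale == "relative" and values.size:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                i = int(np.argmax(bad))
                raise TableError(
                    f"relative table row for sample {df.index[i]!r} sums to "
                    f"{sums[i]!r}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], self.scale)

    def select_features(self, feature_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(feature_ids)], self.scale)


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample outcome labels and optional cluster assignments."""

    data: pd.DataFrame  # index: sample_id; columns: outcome, cluster

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        if "outcome" not in df.columns:
            raise TableError("sample frame requires an 'outcome' column")
        bad = ~df["outcome"].isin([OUTCOME_CASE, OUTCOME_CONTROL])
        if bad.any():
            raise TableError(
                f"outcome must be 'case' or 'control'; offending samples: "
                f"{df.index[bad].tolist()[:5]}"
            )
        if "cluster" not in df.columns:
            object.__setattr__(
                self, "data", df.assign(cluster=pd.Series(pd.NA, index=df.index))
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def outcome(self) -> pd.Series:
        return self.data["outcome"]

    @property
    def cluster(self) -> pd.Series:
        return self.data["cluster"]

    def case_ids(self) -> list[str]:
        return list(self.data.index[self.data["outcome"] == OUTCOME_CASE])

    def control_ids(self) -> list[str]:
        return list(self.data.index[self.data["outcome"] == OUTCOME_CONTROL])

    def with_cluster(self, labels: pd.Series) -> "SampleFrame":
        df = self.data.copy()
        df["cluster"] = labels.reindex(df.index)
        return SampleFrame(df)

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class FeatureAnnotation:
    """KO → level-1 (and optional level-2) functional-category map.

    Each feature maps to exactly one level-1 category; upstream annotation is
    responsible for resolving KOs with multiple KEGG assignments to a single
    category before entry here.
    """

    data: pd.DataFrame  # index: feature_id; columns: category_l1, category_l2

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "feature")
        if "category_l1" not in df.columns:
            raise TableError("annotation requires a 'category_l1' column")
        if df["category_l1"].isna().any():
            missing = df.index[df["category_l1"].isna()].tolist()
            raise TableError(f"features without category_l1: {missing[:5]}")
        if "category_l2" not in df.columns:
            object.__setattr__(
                self, "data", df.assign(category_l2=pd.Series(pd.NA, index=df.index))
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def category_l1(self) -> pd.Series:
        return self.data["category_l1"]

    def categories(self) -> list[str]:
        return sorted(self.data["category_l1"].unique())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, scale_hint: str | None = None) -> AbundanceTable:
    """Read a TSV abundance table (rows = samples, columns = features).

    The scale is inferred — rows all summing to 1 within 1e-6 means
    ``relative`` — unless ``scale_hint`` is given.  Relative tables read from
    disk are re-normalized row-wise to remove round-trip rounding at the
    1e-6 level before validation at 1e-9.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise TableError(
                    f"malformed numeric cell at sample {row!r}, feature {col!r} "
                    f"in {path}"
                ) from exc
        raise
    values = df.to_numpy()
    if values.size and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise TableError(
            f"negative value at sample {df.index[i]!r}, feature {df.columns[j]!r} "
            f"in {path}"
        )
    if scale_hint is not None:
        scale = scale_hint
    else:
        sums = values.sum(axis=1)
        scale = "relative" if values.size and np.allclose(sums, 1.0, atol=_INFER_TOL) else "counts"
    if scale == "relative" and values.size:
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            raise TableError(f"all-zero sample row in relative table {path}")
        df = df.div(sums, axis=0)
    return AbundanceTable(df, scale)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a TSV with full float precision so read(write(T)) round-trips."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(Path(path), sep="\t", float_format="%.17g")


def read_sample_frame(path: str | Path) -> SampleFrame:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path: str | Path) -> None:
    df = frame.data.copy()
    df.index.name = "sample_id"
    df.to_csv(Path(path), sep="\t")


def read_feature_annotation(path: str | Path) -> FeatureAnnotation:
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return FeatureAnnotation(df)


def write_feature_annotation(annotation: FeatureAnnotation, path: str | Path) -> None:
    df = annotation.data.copy()
    df.index.name = "feature_id"
    df.to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Row-normalize to relative abundances; idempotent.

    Raises :class:`TableError` for any all-zero sample row, naming the sample.
    """
    sums = table.data.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise TableError(
            f"cannot normalize all-zero sample row(s): {table.data.index[zero].tolist()[:5]}"
        )
    return AbundanceTable(table.data.div(sums, axis=0), "relative")


def align_samples(
    tables: Sequence[AbundanceTable], frame: SampleFrame | None = None
) -> tuple[list[AbundanceTable], SampleFrame | None]:
    """Restrict tables (and optionally the metadata frame) to shared samples.

    The canonical order is the first table's sample order filtered to the
    intersection; every output shares it exactly.
    """
    if not tables:
        raise TableError("no tables to align")
    shared = set(tables[0].sample_ids)
    for t in tables[1:]:
        shared &= set(t.sample_ids)
    if frame is not None:
        shared &= set(frame.sample_ids)
    if not shared:
        raise TableError("sample-ID intersection across tables is empty")
    order = [s for s in tables[0].sample_ids if s in shared]
    aligned = [t.select_samples(order) for t in tables]
    aligned_frame = frame.select_samples(order) if frame is not None else None
    return aligned, aligned_frame
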