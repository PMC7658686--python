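"""Tabular I/O and container types for functional-abundance analysis.

The pipeline operates on three tables, all TSV with a header row:

* an abundance table — samples in rows, functions (COG IDs) in columns,
  plus a reserved ``group`` column carrying the study-group label;
* a category map — ``function`` / ``category`` / ``class`` columns mapping
  each COG to its one-letter COG category and one of the four broad
  functional classes;
* a clinical table — samples in rows, numeric clinical indices in columns,
  plus the same reserved ``group`` column.

Sample order and group labels must agree between abundance and clinical
tables when they are used jointly; a mismatch is an error, never a join.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_COLUMN = "group"

#: The four broad COG functional classes and their one-letter categories.
CLASS_OF_CATEGORY: dict[str, str] = {}
FUNCTIONAL_CLASSES = (
    "information storage and processing",
    "cellular processes and signaling",
    "metabolism",
    "poorly characterized",
)
for _cat in "JAKLB":
    CLASS_OF_CATEGORY[_cat] = FUNCTIONAL_CLASSES[0]
for _cat in "DYVTMNZWUOX":
    CLASS_OF_CATEGORY[_cat] = FUNCTIONAL_CLASSES[1]
for _cat in "CGEFHIPQ":
    CLASS_OF_CATEGORY[_cat] = FUNCTIONAL_CLASSES[2]
for _cat in "RS":
    CLASS_OF_CATEGORY[_cat] = FUNCTIONAL_CLASSES[3]


class TableFormatError(ValueError):
    """Raised when an input table violates the expected layout or invariants."""


@dataclass
class FunctionalProfile:
    """Sample x function abundance matrix with per-sample group labels.

    ``data`` holds one row per sample and one column per function; ``unit``
    is ``"counts"`` (non-negative, unconstrained row sums) or ``"relative"``
    (every row sums to 1).
    """

    data: pd.DataFrame
    group: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "relative"):
            raise ValueError(f"unit must be 'counts' or 'relative', got {self.unit!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample ID: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise TableFormatError(f"duplicate function ID: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise TableFormatError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"function {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"function {self.data.columns[c]!r}"
            )
        if self.unit == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[int(np.argmax(np.abs(sums - 1.0)))]
                raise TableFormatError(f"relative-unit row does not sum to 1: {bad!r}")
        if not self.group.index.equals(self.data.index):
            raise TableFormatError("group labels do not align with sample IDs")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def function_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def groups(self) -> list:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.group))

    def subset_group(self, label) -> "FunctionalProfile":
        mask = (self.group == label).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown group label: {label!r}")
        return FunctionalProfile(self.data.loc[mask], self.group.loc[mask], self.unit)


@dataclass
class CategoryMap:
    """Maps each function ID to a one-letter COG category and broad class."""

    entries: pd.DataFrame  # index: function ID; columns: category, class

    def __post_init__(self) -> None:
        missing = {"category", "class"} - set(self.entries.columns)
        if missing:
            raise TableFormatError(f"category map missing columns: {sorted(missing)}")
        if self.entries.index.duplicated().any():
            dup = self.entries.index[self.entries.index.duplicated()][0]
            raise TableFormatError(f"duplicate function ID in category map: {dup!r}")
        # each category must belong to exactly one class
        per_cat = self.entries.groupby("category")["class"].nunique()
        if (per_cat > 1).any():
            bad = per_cat.index[per_cat > 1][0]
            raise TableFormatError(f"category {bad!r} maps to more than one class")

    def category_of(self, function_id) -> str:
        try:
            return self.entries.at[function_id, "category"]
        except KeyError:
            raise KeyError(f"function {function_id!r} not in category map") from None

    def class_of(self, function_id) -> str:
        try:
            return self.entries.at[function_id, "class"]
        except KeyError:
            raise KeyError(f"function {function_id!r} not in category map") from None

    def unmapped(self, function_ids) -> list:
        known = set(self.entries.index)
        return [f for f in function_ids if f not in known]


@dataclass
class ClinicalTable:
    """Sample x clinical-index table with group labels; NaN marks missing."""

    data: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample ID: {dup!r}")
        if not self.group.index.equals(self.data.index):
            raise TableFormatError("group labels do not align with sample IDs")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def index_names(self) -> list:
        return list(self.data.columns)

    def check_aligned(self, profile: FunctionalProfile) -> None:
        """Require identical sample IDs and group labels, in order."""
        if list(self.data.index) != list(profile.data.index):
            raise TableFormatError("clinical and abundance sample IDs differ")
        if list(self.group) != list(profile.group):
            raise TableFormatError("clinical and abundance group labels differ")


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_table(path, *, transpose: bool = False) -> FunctionalProfile:
    """Read a TSV abundance table into a :class:`FunctionalProfile`.

    Expects samples in rows and a ``group`` column; ``transpose=True``
    accepts the functions-in-rows orientation (the group row then sits in a
    row labelled ``group``). Unit is inferred: rows all summing to ~1 are
    taken as relative abundances, anything else as counts.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        frame = frame.T
    if GROUP_COLUMN not in frame.columns:
        raise TableFormatError(f"abundance table lacks a {GROUP_COLUMN!r} column")
    group = frame[GROUP_COLUMN].astype(str)
    values = frame.drop(columns=[GROUP_COLUMN])
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric abundance value: {exc}") from exc
    if values.isna().to_numpy().any():
        raise TableFormatError("ragged or missing abundance entries")
    sums = values.to_numpy().sum(axis=1)
    unit = "relative" if np.allclose(sums, 1.0, atol=1e-6) else "counts"
    return FunctionalProfile(values, group, unit)


def write_abundance_table(profile: FunctionalProfile, path) -> None:
    out = profile.data.copy()
    out.insert(0, GROUP_COLUMN, profile.group)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_category_map(path) -> CategoryMap:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return CategoryMap(frame)


def write_category_map(cmap: CategoryMap, path) -> None:
    out = cmap.entries.copy()
    out.index.name = "function"
    out.to_csv(path, sep="\t")


def read_clinical_table(path) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if GROUP_COLUMN not in frame.columns:
        raise TableFormatError(f"clinical table lacks a {GROUP_COLUMN!r} column")
    group = frame[GROUP_COLUMN].astype(str)
    data = frame.drop(columns=[GROUP_COLUMN]).astype(float)
    return ClinicalTable(data, group)


def write_clinical_table(table: ClinicalTable, path) -> None:
    out = table.data.copy()
    out.insert(0, GROUP_COLUMN, table.group)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transforms


def normalize_relative(profile: FunctionalProfile) -> FunctionalProfile:
    """Close each sample row to proportions (unit becomes ``relative``)."""
    if profile.unit == "relative":
        return profile
    values = profile.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    if (sums == 0).any():
        bad = profile.data.index[int(np.argmax(sums == 0))]
        raise ValueError(f"all-zero abundance row for sample {bad!r}")
    rel = pd.DataFrame(
        values / sums[:, None], index=profile.data.index, columns=profile.data.columns
    )
    return FunctionalProfile(rel, profile.group, "relative")


def aggregate_by_category(
    profile: FunctionalProfile,
    cmap: CategoryMap,
    level: str = "category",
    *,
    allow_unmapped: bool = False,
) -> FunctionalProfile:
    """Sum abundance columns within COG category or broad functional class.

    Per-sample totals are conserved. Unmapped functions raise unless
    ``allow_unmapped``, in which case they are pooled under ``"unmapped"``.
    """
    if level not in ("category", "class"):
        raise ValueError(f"level must be 'category' or 'class', got {level!r}")
    unmapped = cmap.unmapped(profile.function_ids)
    if unmapped and not allow_unmapped:
        raise KeyError(f"unmapped function IDs: {unmapped}")
    key = cmap.entries[level]
    labels = [
        key[f] if f in key.index else "unmapped" for f in profile.function_ids
    ]
    grouped = profile.data.T.groupby(pd.Index(labels, name=level)).sum().T
    return FunctionalProfile(grouped, profile.group, profile.unit)


def class_fractions(
    profile: FunctionalProfile, cmap: CategoryMap
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample and cohort-mean abundance fraction of each functional class.

    Requires relative units; returns ``(per_sample, cohort_mean)`` where each
    per-sample row sums to 1 and the cohort mean is the unweighted mean over
    samples.
    """
    if profile.unit != "relative":
        raise ValueError("class_fractions requires relative units")
    agg = aggregate_by_category(profile, cmap, "class")
    per_sample = agg.data
    return per_sample, per_sample.mean(axis=0)
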