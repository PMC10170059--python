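"""Tabular I/O for expression (TPM) matrices, sample sheets and Ct tables.

All on-disk formats are plain delimited text. The expression matrix and Ct
table are wide (genes in rows, samples in columns) with a ``gene_id`` header
in the first column. The sample sheet is long, one row per sample, with
columns ``sample_id``, ``condition``, ``replicate`` and optionally ``group``.

The delimiter is auto-detected from the header line (tab wins over comma);
an explicit ``delimiter=`` overrides detection. Gene and sample identifiers
are opaque, case-sensitive strings — assembly-style ids containing dots
(e.g. ``evm.model.Hic_asm_9.985.3``) pass through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CtMatrix",
    "SampleSheet",
    "read_expression_matrix",
    "read_sample_sheet",
    "read_ct_table",
    "write_expression_matrix",
    "write_ct_table",
    "write_sample_sheet",
    "write_table",
]

#: Ct values outside this open interval trigger a warning (not an error):
#: a quantification cycle beyond the plate's cycling range is suspicious
#: but may still be meaningful (e.g. extrapolated values).
CT_SANITY_RANGE = (0.0, 45.0)

#: Tokens accepted as "missing" in Ct tables; "NA" is written back out.
NA_TOKENS = ("", "NA")


def _detect_delimiter(path: Path) -> str:
    header = Path(path).open("r", encoding="utf-8").readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(f"{path}: cannot detect delimiter (no tab or comma in header)")


def _check_unique(labels, what: str, where: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for x in labels:
        seen[x] = seen.get(x, 0) + 1
    dupes = sorted(x for x, k in seen.items() if k > 1)
    if dupes:
        raise ValueError(f"{where}: duplicate {what} ids: {', '.join(map(str, dupes))}")


@dataclass
class SampleSheet:
    """Per-sample metadata: condition (stage/tissue/timepoint), replicate, group."""

    table: pd.DataFrame  # columns: sample_id, condition, replicate [, group]

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(self.table["sample_id"], "sample", "sample sheet")
        pairs = list(zip(self.table["condition"], self.table["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("sample sheet: (condition, replicate) pairs not unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def condition_of_sample(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["condition"]))

    @property
    def group_of_sample(self) -> dict[str, str] | None:
        if "group" not in self.table.columns:
            return None
        return dict(zip(self.table["sample_id"], self.table["group"]))


@dataclass
class ExpressionMatrix:
    """Gene × sample TPM matrix with a condition label per sample.

    ``values`` is a float DataFrame indexed by gene id with sample ids as
    columns; entries are finite, non-negative TPM. Replicates of the same
    biological condition share a label in ``condition_of_sample``.
    """

    values: pd.DataFrame
    condition_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene", "expression matrix")
        _check_unique(self.values.columns, "sample", "expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"expression matrix: non-finite TPM at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"expression matrix: negative TPM at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        if not self.condition_of_sample:
            # degenerate default: every sample is its own condition
            self.condition_of_sample = {s: s for s in self.values.columns}
        missing = [s for s in self.values.columns if s not in self.condition_of_sample]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (column) order."""
        seen: list[str] = []
        for s in self.values.columns:
            c = self.condition_of_sample[s]
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class CtMatrix:
    """Gene × sample quantification-cycle matrix; NaN marks missing wells."""

    values: pd.DataFrame
    group_of_sample: dict[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene", "Ct table")
        _check_unique(self.values.columns, "sample", "Ct table")
        arr = self.values.to_numpy(dtype=float)
        observed = arr[~np.isnan(arr)]
        lo, hi = CT_SANITY_RANGE
        if observed.size and ((observed <= lo) | (observed >= hi)).any():
            warnings.warn(
                f"Ct values outside the typical ({lo}, {hi}) cycle range",
                stacklevel=3,
            )
        if self.group_of_sample is not None:
            missing = [s for s in self.values.columns if s not in self.group_of_sample]
            if missing:
                raise ValueError(f"samples without group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the Ct value is missing."""
        return self.values.isna()


# ---------------------------------------------------------------------------
# readers


def _read_wide(path, delimiter):
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id column plus sample columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return path, df


def _to_float(df: pd.DataFrame, path, allow_na: bool) -> pd.DataFrame:
    out = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if allow_na and cell in NA_TOKENS:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_sample_sheet(path, delimiter: str | None = None) -> SampleSheet:
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "condition": str})
    return SampleSheet(df)


def read_expression_matrix(
    path,
    sample_sheet_path=None,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a genes × samples TPM table, validated against its sample sheet.

    Row and column order are preserved exactly as in the file. Any sample
    present in the matrix but absent from the sheet is a hard error.
    """
    path, df = _read_wide(path, delimiter)
    values = _to_float(df, path, allow_na=False)
    conditions: dict[str, str] = {}
    if sample_sheet_path is not None:
        sheet = (
            sample_sheet_path
            if isinstance(sample_sheet_path, SampleSheet)
            else read_sample_sheet(sample_sheet_path, delimiter=delimiter)
        )
        absent = [s for s in values.columns if s not in sheet.condition_of_sample]
        if absent:
            raise ValueError(f"{path}: samples not in sample sheet: {absent}")
        conditions = {s: sheet.condition_of_sample[s] for s in values.columns}
    return ExpressionMatrix(values, conditions)


def read_ct_table(
    path,
    sample_sheet_path=None,
    group_column: str | None = None,
    delimiter: str | None = None,
) -> CtMatrix:
    """Read a wide Ct table; empty cells and "NA" become missing values.

    When ``group_column`` names a sample-sheet column, its labels are
    attached as the per-sample group (used by grouped NormFinder).
    """
    path, df = _read_wide(path, delimiter)
    values = _to_float(df, path, allow_na=True)
    groups = None
    if group_column is not None:
        if sample_sheet_path is None:
            raise ValueError("group_column requires a sample sheet")
        sheet = (
            sample_sheet_path
            if isinstance(sample_sheet_path, SampleSheet)
            else read_sample_sheet(sample_sheet_path, delimiter=delimiter)
        )
        if group_column not in sheet.table.columns:
            raise ValueError(f"sample sheet has no column {group_column!r}")
        lut = dict(zip(sheet.table["sample_id"], sheet.table[group_column]))
        absent = [s for s in values.columns if s not in lut]
        if absent:
            raise ValueError(f"{path}: samples not in sample sheet: {absent}")
        groups = {s: str(lut[s]) for s in values.columns}
    return CtMatrix(values, groups)


# ---------------------------------------------------------------------------
# writers

# full precision for data matrices so a write/read round trip is bit-exact
_FULL = "%.17g"


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    m.values.to_csv(path, sep=delimiter, index_label="gene_id", float_format=_FULL)


def write_ct_table(ct: CtMatrix, path, delimiter: str = "\t") -> None:
    ct.values.to_csv(
        path, sep=delimiter, index_label="gene_id", float_format=_FULL, na_rep="NA"
    )


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str = "\t") -> None:
    sheet.table.to_csv(path, sep=delimiter, index=False)


def write_table(rows: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a result table with fixed 6-significant-digit float formatting.

    Column order is the DataFrame's own (deterministic by construction of
    each result type); an empty table is an error rather than a headerless
    file.
    """
    if rows is None or len(rows) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    rows.to_csv(path, sep=delimiter, index=False, float_format="%.6g", na_rep="NA")
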