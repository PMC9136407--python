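"""Reading, validating and partitioning merged sample tables.

The expected input is a single delimiter-separated file with a header row
and three blocks of columns: a sample-ID column (first by default), ``n``
clinical-metadata columns (each all-string or all-numeric), and ``m``
feature-abundance columns (relative or absolute, non-negative).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Tokens treated as missing values on input (in addition to empty cells).
MISSING_TOKENS = frozenset({"", "NA", "na", "NaN"})

_EXTENSION_DELIMITERS = {".csv": ",", ".tsv": "\t", ".tab": "\t", ".txt": "\t"}


class TableFormatError(ValueError):
    """The input file violates the merged-table contract."""


class MixedTypeColumnError(TableFormatError):
    """A column mixes numeric and non-numeric entries."""

    def __init__(self, column: str, row_label: object, value: object):
        self.column = column
        self.row_label = row_label
        self.value = value
        super().__init__(
            f"column {column!r} mixes strings and numbers: value {value!r} at "
            f"row {row_label!r} (each column must be all-string or all-numeric)"
        )


@dataclass
class RawTable:
    """A parsed but not yet partitioned merged table.

    ``frame`` is indexed by sample ID; ``kinds`` records, per column,
    whether it parsed as ``"numeric"`` or ``"string"``.
    """

    frame: pd.DataFrame
    kinds: dict[str, str]
    sample_id_col: str

    @property
    def n_samples(self) -> int:
        return len(self.frame)


@dataclass
class SampleTable:
    """The partitioned table: metadata columns and numeric feature columns.

    Both frames share the sample-ID index. Feature values are finite and
    non-negative; metadata columns may contain missing values.
    """

    metadata: pd.DataFrame
    features: pd.DataFrame
    sample_id_col: str = "sample_id"
    metadata_kinds: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.metadata.index.equals(self.features.index):
            raise ValueError("metadata and features must share the sample index")
        if self.features.shape[1] == 0:
            raise TableFormatError("no feature columns")
        ids = self.metadata.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample IDs: {dupes}")
        vals = self.features.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.features.columns[~np.isfinite(vals).all(axis=0)].tolist()
            raise TableFormatError(f"non-finite feature values in columns {bad}")
        if (vals < 0).any():
            bad = self.features.columns[(vals < 0).any(axis=0)].tolist()
            raise TableFormatError(f"negative feature values in columns {bad}")

    @property
    def sample_ids(self) -> list:
        return self.metadata.index.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    def to_frame(self) -> pd.DataFrame:
        """Re-merge into the one-table input layout (ID, metadata, features)."""
        merged = pd.concat([self.metadata, self.features], axis=1)
        merged.index.name = self.sample_id_col
        return merged


def _infer_delimiter(path: Path) -> str:
    delim = _EXTENSION_DELIMITERS.get(path.suffix.lower())
    if delim is not None:
        return delim
    header = path.open("r", newline="").readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error as exc:  # pragma: no cover - depends on sniffing heuristics
        raise TableFormatError(
            f"cannot infer the delimiter of {path.name}; pass one explicitly"
        ) from exc


def _classify_column(col: pd.Series) -> tuple[str, pd.Series]:
    """Return ("numeric"|"string", converted column), or raise on a mixture."""
    present = col[col.notna()]
    numeric = pd.to_numeric(present, errors="coerce")
    n_num = int(numeric.notna().sum())
    if n_num == len(present) and len(present) > 0:
        return "numeric", pd.to_numeric(col, errors="coerce").astype(float)
    if 0 < n_num < len(present):
        offender = present[numeric.isna()].index[0]
        raise MixedTypeColumnError(str(col.name), offender, present[offender])
    return "string", col


def read_merged_table(
    path: str | Path,
    delimiter: str | None = None,
    sample_id_col: str | int = 0,
) -> RawTable:
    """Read a merged CSV/TSV table and type every column.

    The delimiter, when not given, is inferred from the file extension and,
    failing that, sniffed from the header line. Missing values are the
    tokens in :data:`MISSING_TOKENS`. Each column comes back either fully
    numeric (float, NaN for missing) or string-valued; mixed columns raise
    :class:`MixedTypeColumnError`. By default the first column is the
    sample ID; pass a name or position to override.
    """
    path = Path(path)
    if not path.is_file():
        raise TableFormatError(f"cannot read input table: {path}")
    if delimiter is None:
        delimiter = _infer_delimiter(path)

    frame = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    frame = frame.map(lambda v: np.nan if v.strip() in MISSING_TOKENS else v.strip())

    if frame.shape[1] < 3:
        raise TableFormatError(
            f"{path.name}: expected at least 3 columns "
            f"(sample ID, metadata, features), found {frame.shape[1]}"
        )
    if len(frame) < 2:
        raise TableFormatError(f"{path.name}: expected at least 2 data rows")

    id_col = frame.columns[sample_id_col] if isinstance(sample_id_col, int) else sample_id_col
    if id_col not in frame.columns:
        raise TableFormatError(f"sample-ID column {id_col!r} not found")
    ids = frame[id_col]
    if ids.isna().any():
        raise TableFormatError("empty sample IDs found")
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate sample IDs: {dupes}")

    frame = frame.set_index(id_col)
    kinds: dict[str, str] = {}
    converted = {}
    for name in frame.columns:
        kinds[name], converted[name] = _classify_column(frame[name])
    out = pd.DataFrame(converted, index=frame.index)[frame.columns]
    return RawTable(frame=out, kinds=kinds, sample_id_col=id_col)


def partition_columns(raw: RawTable, schema) -> SampleTable:
    """Split a raw table into metadata and features according to a schema.

    Columns named by the schema (random or fixed variables) become
    metadata; every remaining column becomes a feature and must be numeric.
    """
    declared = list(schema.random_vars) + list(schema.fixed_vars)
    missing = [v for v in declared if v not in raw.frame.columns]
    if missing:
        raise TableFormatError(f"schema references missing columns: {missing}")
    feature_cols = [c for c in raw.frame.columns if c not in declared]
    if not feature_cols:
        raise TableFormatError("no feature columns: every column was declared as metadata")
    non_numeric = [c for c in feature_cols if raw.kinds[c] != "numeric"]
    if non_numeric:
        raise TableFormatError(
            f"leftover feature columns must be numeric; string-typed: {non_numeric}"
        )
    features = raw.frame[feature_cols].astype(float)
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise TableFormatError(f"missing values in feature columns {bad}")
    return SampleTable(
        metadata=raw.frame[declared].copy(),
        features=features,
        sample_id_col=raw.sample_id_col,
        metadata_kinds={c: raw.kinds[c] for c in declared},
    )


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Canonical TSV writer used for every tabular result.

    Floats are written with shortest round-trip repr so re-reading
    reproduces values exactly; line endings are fixed for byte-stable
    output across platforms.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n", na_rep="NA")
    return path
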