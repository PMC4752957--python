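"""Data model for factorial mating designs and replicate-count expansion.

An :class:`ObservationTable` is a thin wrapper around a pandas DataFrame
holding one row per individual offspring, plus the binding of column
names to design roles (dam, sire, family, replicate, positions, block).
A :class:`CountTable` holds replicate-level outcome counts and can be
expanded to the individual level with :func:`expand_binary` or
:func:`expand_multi`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError, ValidationError, ConfigurationError

__all__ = [
    "ObservationTable",
    "CountTable",
    "DesignSummary",
    "expand_binary",
    "expand_multi",
    "validate_design",
    "read_observations",
    "read_counts",
]

#: name of the response column created by the expansion operations
STATUS_COLUMN = "status"


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c is not None and c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing column(s): {missing}")


def _derive_family(df: pd.DataFrame, dam: str, sire: str) -> pd.Series:
    # role-prefixed keys so dam "1" can never collide with sire "1"
    return "d:" + df[dam].astype(str) + "|s:" + df[sire].astype(str)


@dataclass
class ObservationTable:
    """Individual-level records of a factorial mating design.

    Parameters
    ----------
    data
        One row per offspring.  Identifier columns are treated as opaque
        labels (no numeric coercion).
    dam, sire
        Column names of the parental identifiers.
    family
        Optional dam×sire family column.  When absent a ``family``
        column is derived as the role-prefixed dam⊗sire combination;
        when present it is checked for consistency (each dam/sire pair
        must map to exactly one family label and vice versa).
    replicate, positions, block
        Optional further design identifiers.
    """

    data: pd.DataFrame
    dam: str = "dam"
    sire: str = "sire"
    family: str | None = None
    replicate: str | None = None
    positions: tuple[str, ...] = ()
    block: str | None = None

    def __post_init__(self) -> None:
        self.positions = tuple(self.positions)
        df = self.data
        _require_columns(df, [self.dam, self.sire], "observation table")
        _require_columns(
            df,
            [self.replicate, self.block, *self.positions],
            "observation table",
        )
        for col in (self.dam, self.sire):
            if df[col].isna().any():
                raise ValidationError(f"identifier column {col!r} has missing values")
        if self.family is None:
            df = df.copy()
            df["family"] = _derive_family(df, self.dam, self.sire)
            self.family = "family"
            self.data = df
        else:
            _require_columns(df, [self.family], "observation table")
            pairs = df.groupby([self.dam, self.sire], observed=True)[self.family].nunique()
            if (pairs > 1).any():
                raise ValidationError(
                    "family column is inconsistent: some dam/sire pairs map to "
                    "multiple family labels"
                )
            fams = df.groupby(self.family, observed=True).apply(
                lambda g: g[[self.dam, self.sire]].drop_duplicates().shape[0],
                include_groups=False,
            )
            if (fams > 1).any():
                raise ValidationError(
                    "family column is inconsistent: some family labels span "
                    "multiple dam/sire pairs"
                )

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def identifier_columns(self) -> list[str]:
        cols = [self.dam, self.sire, self.family]
        if self.replicate:
            cols.append(self.replicate)
        cols.extend(self.positions)
        if self.block:
            cols.append(self.block)
        return cols

    def check_response(self, response: str, kind: str = "continuous") -> None:
        """Validate the response column for a given data kind.

        ``kind`` is one of ``continuous``, ``binary`` or ``count``.
        """
        _require_columns(self.data, [response], "observation table")
        y = self.data[response]
        if y.isna().any():
            raise ValidationError(f"response column {response!r} has missing values")
        values = pd.to_numeric(y, errors="coerce")
        if values.isna().any():
            raise ValidationError(f"response column {response!r} is not numeric")
        arr = values.to_numpy(dtype=float)
        if kind == "binary" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValidationError(f"binary response {response!r} must be 0/1")
        if kind == "count" and (
            (arr < 0).any() or not np.allclose(arr, np.round(arr))
        ):
            raise ValidationError(
                f"count response {response!r} must be non-negative integers"
            )

    def with_data(self, data: pd.DataFrame) -> "ObservationTable":
        """Same role bindings, new rows; skips re-validation (hot loops)."""
        obj = object.__new__(type(self))
        obj.data = data
        obj.dam = self.dam
        obj.sire = self.sire
        obj.family = self.family
        obj.replicate = self.replicate
        obj.positions = self.positions
        obj.block = self.block
        return obj

    def subset(self, row_indexer) -> "ObservationTable":
        """Return a new table with a subset (or resampling) of the rows."""
        return self.with_data(self.data.iloc[row_indexer].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class CountTable:
    """Replicate-level records with one or more outcome-count columns."""

    data: pd.DataFrame
    count_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.count_columns = tuple(self.count_columns)
        _require_columns(self.data, self.count_columns, "count table")
        for col in self.count_columns:
            _check_counts(self.data, col)


def _check_counts(df: pd.DataFrame, col: str) -> np.ndarray:
    if col not in df.columns:
        raise SchemaError(f"count column {col!r} not found")
    values = pd.to_numeric(df[col], errors="coerce")
    if values.isna().any():
        raise ValidationError(f"count column {col!r} has missing or non-numeric values")
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError(f"count column {col!r} has negative values")
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"count column {col!r} has non-integer values")
    return arr.astype(np.int64)


def expand_multi(
    counts: CountTable | pd.DataFrame,
    value_map: Mapping[str, float],
    copy_columns: Sequence[str],
) -> pd.DataFrame:
    """Expand outcome counts to one row per offspring.

    ``value_map`` is an ordered mapping from count-column name to the
    numeric code emitted in the new ``status`` column.  For each input
    row the categories are emitted in ``value_map`` order; input row
    order is preserved.  ``copy_columns`` are duplicated onto every
    emitted row.
    """
    df = counts.data if isinstance(counts, CountTable) else counts
    if not value_map:
        raise SchemaError("value_map must name at least one count column")
    codes = list(value_map.values())
    if len(set(codes)) != len(codes):
        raise ConfigurationError(f"duplicate codes in value_map: {codes}")
    _require_columns(df, list(copy_columns), "count table")
    count_arrays = {col: _check_counts(df, col) for col in value_map}

    n = len(df)
    # per input row: category blocks in value_map order
    per_row = np.zeros(n, dtype=np.int64)
    for arr in count_arrays.values():
        per_row += arr
    row_idx = np.empty(int(per_row.sum()), dtype=np.int64)
    status = np.empty(int(per_row.sum()), dtype=float)
    pos = 0
    col_list = list(value_map.items())
    counts_mat = np.column_stack([count_arrays[c] for c, _ in col_list])
    for i in range(n):
        for j, (_, code) in enumerate(col_list):
            k = counts_mat[i, j]
            if k:
                row_idx[pos : pos + k] = i
                status[pos : pos + k] = code
                pos += k
    out = df.iloc[row_idx][list(copy_columns)].reset_index(drop=True)
    if np.allclose(status, np.round(status)):
        out[STATUS_COLUMN] = status.astype(np.int64)
    else:
        out[STATUS_COLUMN] = status
    return out


def expand_binary(
    counts: CountTable | pd.DataFrame,
    one_column: str,
    zero_column: str,
    copy_columns: Sequence[str],
) -> pd.DataFrame:
    """Expand a success/failure count pair to one 0/1 row per offspring.

    Rows counted in ``one_column`` get ``status`` 1 and precede the
    ``zero_column`` rows of the same input row.
    """
    return expand_multi(counts, {one_column: 1, zero_column: 0}, copy_columns)


@dataclass
class DesignSummary:
    """Result of :func:`validate_design`."""

    n_dam: int
    n_sire: int
    n_family: int
    family_sizes: dict[str, int] = field(repr=False)
    missing_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_complete(self) -> bool:
        return not self.missing_cells


def validate_design(table: ObservationTable) -> DesignSummary:
    """Summarize the factorial design and list absent dam×sire cells."""
    df = table.data
    dams = df[table.dam].astype(str).unique()
    sires = df[table.sire].astype(str).unique()
    if len(dams) < 2 or len(sires) < 2:
        raise DesignError(
            f"need at least 2 dams and 2 sires to identify variance components "
            f"(got {len(dams)} dam(s), {len(sires)} sire(s))"
        )
    present = set(
        zip(df[table.dam].astype(str), df[table.sire].astype(str))
    )
    missing = sorted(
        (d, s) for d in dams for s in sires if (d, s) not in present
    )
    sizes = df.groupby(table.family, observed=True).size()
    return DesignSummary(
        n_dam=len(dams),
        n_sire=len(sires),
        n_family=int(sizes.shape[0]),
        family_sizes=sizes.to_dict(),
        missing_cells=missing,
    )


def read_observations(path, **roles) -> ObservationTable:
    """Read an :class:`ObservationTable` from a UTF-8 CSV with header."""
    return ObservationTable(pd.read_csv(path), **roles)


def read_counts(path, count_columns: Sequence[str] = ()) -> CountTable:
    """Read a :class:`CountTable` from a UTF-8 CSV with header."""
    return CountTable(pd.read_csv(path), count_columns=tuple(count_columns))
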