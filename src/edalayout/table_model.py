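"""Typed tabular data model.

Reads rectangular CSV/TSV data into a :class:`TypedTable`: an ordered set of
role-tagged columns (numeric / categorical / boolean / identifier /
tooltip-only) plus an explicit row-by-column missingness mask. Both plotting
engines consume this structure; neither ever touches raw CSV.

Role inference rule (user overrides always win):

* every non-missing entry parses as a finite number and either some value is
  non-integer or the number of distinct values exceeds ``max_levels``
  → ``numeric``;
* every non-missing entry is a true/false synonym → ``boolean``;
* otherwise → ``categorical`` (including all-missing columns, which get an
  empty level list).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._errors import CoercionError, ConfigError, ContractError, InputFormatError

__all__ = [
    "Role",
    "ColumnSpec",
    "TypedTable",
    "ColumnSummary",
    "DEFAULT_NA_TOKENS",
    "infer_role",
    "coerce",
    "read_table",
    "write_table",
    "table_to_csv",
    "summarise",
]

DEFAULT_NA_TOKENS: frozenset[str] = frozenset({"", "NA", "na", "NaN"})

_TRUE_SYNONYMS = frozenset({"true", "t"})
_FALSE_SYNONYMS = frozenset({"false", "f"})
_BOOL_SYNONYMS = _TRUE_SYNONYMS | _FALSE_SYNONYMS

DEFAULT_MAX_LEVELS = 5


class Role(str, Enum):
    NUMERIC = "numeric"
    CATEGORICAL = "categorical"
    BOOLEAN = "boolean"
    IDENTIFIER = "identifier"
    TOOLTIP = "tooltip-only"


@dataclass(frozen=True)
class ColumnSpec:
    """Name, role and (for discrete roles) the ordered level list of a column."""

    name: str
    role: Role
    levels: tuple[str, ...] = ()
    declared: bool = False

    def __post_init__(self) -> None:
        if self.role in (Role.CATEGORICAL, Role.BOOLEAN):
            if len(set(self.levels)) != len(self.levels):
                raise ContractError(f"column {self.name!r}: duplicate levels")
        elif self.levels:
            raise ContractError(
                f"column {self.name!r}: role {self.role.value} must not carry levels"
            )

    @property
    def is_discrete(self) -> bool:
        return self.role in (Role.CATEGORICAL, Role.BOOLEAN)


@dataclass
class TypedTable:
    """Validated rectangular table with per-column roles and a missingness mask.

    ``values[name]`` is a float64 vector (NaN at missing cells) for numeric
    columns and an object vector of strings (None at missing cells) otherwise.
    ``missing_mask`` has shape ``(n_rows, n_columns)`` in column order.
    """

    columns: list[ColumnSpec]
    values: dict[str, np.ndarray]
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return int(self.missing_mask.shape[0])

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def spec(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def column_index(self, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.name == name:
                return i
        raise KeyError(name)

    def column_missing(self, name: str) -> np.ndarray:
        return self.missing_mask[:, self.column_index(name)]

    def numeric_columns(self) -> list[str]:
        return [c.name for c in self.columns if c.role is Role.NUMERIC]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ContractError("column names must be unique")
        if self.missing_mask.ndim != 2 or self.missing_mask.shape[1] != len(names):
            raise ContractError("missing_mask shape does not match columns")
        n = self.missing_mask.shape[0]
        for j, c in enumerate(self.columns):
            vec = self.values[c.name]
            if len(vec) != n:
                raise ContractError(f"column {c.name!r}: length {len(vec)} != n_rows {n}")
            mask = self.missing_mask[:, j]
            if c.role is Role.NUMERIC:
                if not np.array_equal(np.isnan(vec.astype(float)), mask):
                    raise ContractError(f"column {c.name!r}: NaN pattern disagrees with mask")
            else:
                observed_none = np.array([v is None for v in vec])
                if not np.array_equal(observed_none, mask):
                    raise ContractError(f"column {c.name!r}: None pattern disagrees with mask")
                if c.is_discrete:
                    levelset = set(c.levels)
                    for i, v in enumerate(vec):
                        if v is not None and v not in levelset:
                            raise ContractError(
                                f"column {c.name!r}: value {v!r} at row {i} not in levels"
                            )


@dataclass(frozen=True)
class ColumnSummary:
    name: str
    role: Role
    n_missing: int
    n_distinct: int
    minimum: float | None = None
    maximum: float | None = None


# ---------------------------------------------------------------------------
# role inference


def _parse_number(token: str) -> float | None:
    try:
        x = float(token)
    except ValueError:
        return None
    return x if math.isfinite(x) else None


def infer_role(values: Sequence[str | None], max_levels: int = DEFAULT_MAX_LEVELS) -> Role:
    """Infer a column role from raw string values (``None`` = missing).

    Deterministic; never returns identifier or tooltip roles (those are only
    ever declared by the user). All-missing columns come back categorical.
    """
    if max_levels < 1:
        raise ContractError("max_levels must be positive")
    observed = [v for v in values if v is not None]
    if not observed:
        return Role.CATEGORICAL
    if all(v.strip().lower() in _BOOL_SYNONYMS for v in observed):
        return Role.BOOLEAN
    parsed = [_parse_number(v) for v in observed]
    if all(p is not None for p in parsed):
        any_fractional = any(p != int(p) for p in parsed)  # type: ignore[arg-type]
        n_distinct = len(set(parsed))
        if any_fractional or n_distinct > max_levels:
            return Role.NUMERIC
        return Role.CATEGORICAL
    return Role.CATEGORICAL


# ---------------------------------------------------------------------------
# coercion


def _first_appearance_levels(observed: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for v in observed:
        if v not in seen:
            seen[v] = None
    return tuple(seen)


def coerce(
    header: Sequence[str],
    rows: Sequence[Sequence[str]],
    overrides: Mapping[str, Role | str] | None = None,
    max_levels: int = DEFAULT_MAX_LEVELS,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> TypedTable:
    """Build a TypedTable from parsed CSV content.

    Overrides are applied first; remaining columns pass through
    :func:`infer_role`. The missingness mask is built from the configured NA
    tokens. Categorical levels are ordered by first appearance.
    """
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if list(header).count(h) > 1})
        raise InputFormatError(f"duplicate header name(s): {', '.join(dupes)}")
    overrides = {k: Role(v) for k, v in (overrides or {}).items()}
    unknown = set(overrides) - set(header)
    if unknown:
        raise ConfigError(
            f"override(s) refer to unknown column(s): {', '.join(sorted(unknown))}"
        )
    na = frozenset(na_tokens)
    n_rows = len(rows)
    n_cols = len(header)
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise InputFormatError(
                f"row {i + 1} has {len(row)} fields, expected {n_cols}"
            )

    mask = np.zeros((n_rows, n_cols), dtype=bool)
    columns: list[ColumnSpec] = []
    values: dict[str, np.ndarray] = {}
    for j, name in enumerate(header):
        raw = [rows[i][j] for i in range(n_rows)]
        cell_missing = [v in na for v in raw]
        mask[:, j] = cell_missing
        cooked: list[str | None] = [None if m else v for v, m in zip(raw, cell_missing)]
        declared = name in overrides
        role = overrides[name] if declared else infer_role(cooked, max_levels)
        observed = [v for v in cooked if v is not None]
        if role is Role.NUMERIC:
            vec = np.full(n_rows, np.nan)
            for i, v in enumerate(cooked):
                if v is None:
                    continue
                p = _parse_number(v)
                if p is None:
                    raise CoercionError(
                        f"column {name!r}: cannot coerce value {v!r} at row {i + 1} to numeric"
                    )
                vec[i] = p
            columns.append(ColumnSpec(name, role, declared=declared))
            values[name] = vec
        else:
            levels = _first_appearance_levels(observed) if role in (Role.CATEGORICAL, Role.BOOLEAN) else ()
            columns.append(ColumnSpec(name, role, levels=levels, declared=declared))
            values[name] = np.array(cooked, dtype=object)
    return TypedTable(columns=columns, values=values, missing_mask=mask)


# ---------------------------------------------------------------------------
# I/O


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(
    path: str | Path,
    overrides: Mapping[str, Role | str] | None = None,
    max_levels: int = DEFAULT_MAX_LEVELS,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
    delimiter: str | None = None,
) -> TypedTable:
    """Read a CSV/TSV file (UTF-8, header row) into a TypedTable.

    Delimiter is auto-detected from the extension unless given explicitly.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    try:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=delim)
            try:
                header = next(reader)
            except StopIteration:
                raise InputFormatError(f"{path}: file is empty (no header row)")
            rows = list(reader)
    except OSError as exc:
        raise InputFormatError(f"cannot read {path}: {exc}") from exc
    return coerce(header, rows, overrides=overrides, max_levels=max_levels, na_tokens=na_tokens)


def _format_cell(table: TypedTable, spec: ColumnSpec, i: int) -> str:
    if table.missing_mask[i, table.column_index(spec.name)]:
        return ""
    v = table.values[spec.name][i]
    if spec.role is Role.NUMERIC:
        return repr(float(v))
    return str(v)


def table_to_csv(table: TypedTable, delimiter: str = ",") -> str:
    """Serialise a TypedTable to CSV text (missing cells become empty)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(table.column_names)
    for i in range(table.n_rows):
        writer.writerow([_format_cell(table, spec, i) for spec in table.columns])
    return buf.getvalue()


def write_table(table: TypedTable, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    path.write_text(table_to_csv(table, delimiter=delim), encoding="utf-8")


# ---------------------------------------------------------------------------
# summaries


def summarise(table: TypedTable) -> list[ColumnSummary]:
    """Per-column summary records: role, missing count, distinct count, range."""
    out: list[ColumnSummary] = []
    for j, spec in enumerate(table.columns):
        mask = table.missing_mask[:, j]
        n_missing = int(mask.sum())
        vec = table.values[spec.name]
        if spec.role is Role.NUMERIC:
            observed = vec[~mask]
            n_distinct = len(np.unique(observed))
            mn = float(observed.min()) if observed.size else None
            mx = float(observed.max()) if observed.size else None
            out.append(ColumnSummary(spec.name, spec.role, n_missing, n_distinct, mn, mx))
        else:
            observed_vals = {v for v, m in zip(vec, mask) if not m}
            out.append(ColumnSummary(spec.name, spec.role, n_missing, len(observed_vals)))
    return out
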