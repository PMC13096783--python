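from __future__ import annotations

import numpy as np
import pytest

from edalayout.table_model import ColumnSpec, Role, TypedTable


def make_table(spec: dict[str, tuple[str, list]]) -> TypedTable:
    """Build a TypedTable from {name: (role, values)} — None marks missing.

    Numeric values may be given as floats/ints (None -> NaN); discrete
    values as strings with levels taken in first appearance order.
    """
    columns: list[ColumnSpec] = []
    values: dict[str, np.ndarray] = {}
    names = list(spec)
    n = len(next(iter(spec.values()))[1])
    mask = np.zeros((n, len(names)), dtype=bool)
    for j, (name, (role_str, vals)) in enumerate(spec.items()):
        role = Role(role_str)
        col_missing = np.array([v is None for v in vals])
        mask[:, j] = col_missing
        if role is Role.NUMERIC:
            vec = np.array([np.nan if v is None else float(v) for v in vals])
            columns.append(ColumnSpec(name, role, declared=True))
        else:
            vec = np.array([None if v is None else str(v) for v in vals], dtype=object)
            levels = ()
            if role in (Role.CATEGORICAL, Role.BOOLEAN):
                seen: dict[str, None] = {}
                for v in vec:
                    if v is not None and v not in seen:
                        seen[v] = None
                levels = tuple(seen)
            columns.append(ColumnSpec(name, role, levels=levels, declared=True))
        values[name] = vec
    return TypedTable(columns=columns, values=values, missing_mask=mask)


def random_mixed_table(rng: np.random.Generator, n_rows: int | None = None) -> TypedTable:
    """Random fixture with numeric + categorical columns and scattered missing."""
    if n_rows is None:
        n_rows = int(rng.integers(3, 40))
    n_num = int(rng.integers(2, 5))
    n_cat = int(rng.integers(1, 4))
    spec: dict[str, tuple[str, list]] = {}
    for j in range(n_num):
        vals = [float(v) for v in rng.normal(size=n_rows)]
        for i in range(n_rows):
            if rng.random() < 0.1:
                vals[i] = None
        spec[f"num{j}"] = ("numeric", vals)
    letters = ["a", "b", "c", "d"]
    for j in range(n_cat):
        vals = [letters[int(k)] for k in rng.integers(0, len(letters), size=n_rows)]
        for i in range(n_rows):
            if rng.random() < 0.1:
                vals[i] = None
        spec[f"cat{j}"] = ("categorical", vals)
    return make_table(spec)


@pytest.fixture
def simple_mixed_table() -> TypedTable:
    return make_table(
        {
            "height": ("numeric", [1.2, 3.4, 2.2, None]),
            "weight": ("numeric", [10.0, 20.0, None, 30.0]),
            "group": ("categorical", ["a", "b", "a", "b"]),
        }
    )
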