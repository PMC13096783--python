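"""Seeded synthetic-data generators for tests, docs, and demos.

The flagship fixture emulates a birdwatching log in which one of two
observers routinely skips weekend sessions, producing a count column whose
missingness depends jointly on two categorical variables (observer identity
and weekday/weekend) — a pattern invisible to one-dimensional summaries but
obvious in a tiled layout with missingness glyphs.

Every generator is fully determined by its seed; the mask is applied *after*
the counts are drawn, so missingness is conditionally independent of the
masked magnitudes given (observer, day).
"""

from __future__ import annotations

import numpy as np

from ._errors import ContractError
from .table_model import ColumnSpec, Role, TypedTable

__all__ = [
    "DILIGENT_OBSERVER",
    "LAZY_OBSERVER",
    "OBSERVER_RATES",
    "gen_lazy_birdwatcher",
    "gen_class_mixture",
    "gen_correlated_numeric",
]

DILIGENT_OBSERVER = "Mei"
LAZY_OBSERVER = "Rowan"
OBSERVER_RATES = {DILIGENT_OBSERVER: 6.0, LAZY_OBSERVER: 3.5}

DAY_LEVELS = ("Weekday", "Weekend")


def _numeric_column(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vec = values.astype(float).copy()
    vec[mask] = np.nan
    return vec


def _categorical_column(values: list[str]) -> np.ndarray:
    return np.array(values, dtype=object)


def gen_lazy_birdwatcher(n_rows: int, seed: int, p_skip: float = 1.0) -> TypedTable:
    """Magpie-count log with a two-variable missingness mechanism.

    Columns: ``Magpies`` (numeric count), ``Birdwatcher`` (2 levels),
    ``Day`` (Weekday/Weekend). With probability ``p_skip`` the count is
    masked exactly on rows where the lazy observer was on duty on a weekend;
    no other cell is ever missing.
    """
    if n_rows < 1:
        raise ContractError("n_rows must be >= 1")
    if not (0.0 <= p_skip <= 1.0):
        raise ContractError("p_skip must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    observers = (DILIGENT_OBSERVER, LAZY_OBSERVER)
    who = rng.integers(0, 2, size=n_rows)
    day = rng.integers(0, 2, size=n_rows)  # 0 = Weekday, 1 = Weekend
    rates = np.where(who == 0, OBSERVER_RATES[DILIGENT_OBSERVER], OBSERVER_RATES[LAZY_OBSERVER])
    magpies = rng.poisson(rates)
    skip_draw = rng.random(n_rows)
    lazy_weekend = (who == 1) & (day == 1)
    mask_magpies = lazy_weekend & (skip_draw < p_skip)

    n_cols = 3
    full_mask = np.zeros((n_rows, n_cols), dtype=bool)
    full_mask[:, 0] = mask_magpies
    return TypedTable(
        columns=[
            ColumnSpec("Magpies", Role.NUMERIC, declared=True),
            ColumnSpec("Birdwatcher", Role.CATEGORICAL, levels=observers, declared=True),
            ColumnSpec("Day", Role.CATEGORICAL, levels=DAY_LEVELS, declared=True),
        ],
        values={
            "Magpies": _numeric_column(magpies, mask_magpies),
            "Birdwatcher": _categorical_column([observers[w] for w in who]),
            "Day": _categorical_column([DAY_LEVELS[d] for d in day]),
        },
        missing_mask=full_mask,
    )


def gen_class_mixture(
    n_rows: int,
    seed: int,
    k_classes: int = 3,
    n_informative: int = 3,
    n_noise: int = 5,
    separation: float = 3.0,
) -> TypedTable:
    """Balanced labelled mixture for feature-ranking tests.

    Informative features take class-specific means spaced ``separation``
    standard deviations apart plus unit Gaussian noise; noise features are
    class-independent N(0,1). Feature column order is shuffled per seed so
    ordering tests cannot rely on position; informative columns are named
    ``signal_*`` and noise columns ``noise_*``.
    """
    if n_rows < 1 or n_informative < 1 or n_noise < 0:
        raise ContractError("counts must be positive (n_noise may be zero)")
    if k_classes < 2:
        raise ContractError("k_classes must be >= 2")
    if separation < 0:
        raise ContractError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    levels = tuple(f"class_{c}" for c in range(k_classes))
    base = np.repeat(np.arange(k_classes), (n_rows + k_classes - 1) // k_classes)[:n_rows]
    cls = rng.permutation(base)

    names: list[str] = []
    feats: dict[str, np.ndarray] = {}
    for j in range(n_informative):
        name = f"signal_{j + 1}"
        names.append(name)
        feats[name] = cls * separation + rng.standard_normal(n_rows)
    for j in range(n_noise):
        name = f"noise_{j + 1}"
        names.append(name)
        feats[name] = rng.standard_normal(n_rows)
    order = rng.permutation(len(names))
    shuffled = [names[i] for i in order]

    n_cols = 1 + len(shuffled)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    columns = [ColumnSpec("class", Role.CATEGORICAL, levels=levels, declared=True)]
    values: dict[str, np.ndarray] = {
        "class": _categorical_column([levels[c] for c in cls])
    }
    for name in shuffled:
        columns.append(ColumnSpec(name, Role.NUMERIC, declared=True))
        values[name] = feats[name]
    return TypedTable(columns=columns, values=values, missing_mask=mask)


def gen_correlated_numeric(
    n_rows: int, seed: int, correlation_matrix: np.ndarray
) -> TypedTable:
    """Multivariate-normal numeric table with the requested correlation.

    Useful for emulating size-correlated morphological features in a PCP.
    The matrix must be symmetric positive semi-definite.
    """
    if n_rows < 1:
        raise ContractError("n_rows must be >= 1")
    corr = np.asarray(correlation_matrix, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ContractError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ContractError("correlation matrix must be symmetric")
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ContractError("correlation matrix is not positive semi-definite")
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_rows, corr.shape[0]))
    data = z @ factor.T
    k = corr.shape[0]
    mask = np.zeros((n_rows, k), dtype=bool)
    columns = [ColumnSpec(f"x{j + 1}", Role.NUMERIC, declared=True) for j in range(k)]
    values = {f"x{j + 1}": data[:, j].copy() for j in range(k)}
    return TypedTable(columns=columns, values=values, missing_mask=mask)
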