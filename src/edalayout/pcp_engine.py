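"""Parallel-coordinate-plot layout engine.

Normalises heterogeneous numeric axes onto a shared [0,1] vertical scale,
orders axes either by minimising pairwise polyline crossings (inversion
counts) or by mutual information with a categorical class feature, and emits
per-sample polylines with optional subclass highlighting.

Everything here is deterministic: ties are broken by documented rules, never
by randomness.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from ._errors import ConfigError, ContractError, InputFormatError
from .table_model import Role, TypedTable

__all__ = [
    "NORMALISATIONS",
    "AxisSpec",
    "CrossingMatrix",
    "PolyLine",
    "PcpLayout",
    "PcpOptions",
    "normalise_axis",
    "count_crossings",
    "crossing_matrix",
    "order_axes_min_crossings",
    "mutual_information",
    "default_n_bins",
    "order_axes_by_mi",
    "build_pcp_layout",
]

logger = logging.getLogger(__name__)

NORMALISATIONS = ("minmax", "rank", "zscore")

# axis count at or below which crossing-minimising ordering is solved exactly
EXACT_ORDERING_LIMIT = 8


@dataclass(frozen=True)
class AxisSpec:
    column: str
    normalisation: str
    position: int


@dataclass(frozen=True)
class CrossingMatrix:
    """Symmetric matrix of pairwise polyline-crossing counts between axes."""

    axes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.axes)
        c = self.counts
        if c.shape != (k, k):
            raise ContractError("counts shape does not match axes")
        if not np.array_equal(c, c.T):
            raise ContractError("crossing matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ContractError("crossing matrix diagonal must be zero")
        if np.any(c < 0):
            raise ContractError("crossing counts must be non-negative")


@dataclass(frozen=True)
class PolyLine:
    row: int
    heights: tuple[float, ...]
    foreground: bool = True
    colour_value: str | None = None


@dataclass
class PcpLayout:
    """Renderable PCP geometry: ordered axes plus per-sample polylines."""

    axes: list[AxisSpec]
    polylines: list[PolyLine]
    colour_feature: str | None = None
    highlight_level: str | None = None
    dropped_rows: list[int] = field(default_factory=list)
    mi_scores: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "pcp",
            "axes": [
                {"column": a.column, "normalisation": a.normalisation, "position": a.position}
                for a in self.axes
            ],
            "polylines": [
                {
                    "row": p.row,
                    "heights": list(p.heights),
                    "foreground": p.foreground,
                    "colour_value": p.colour_value,
                }
                for p in self.polylines
            ],
            "colour_feature": self.colour_feature,
            "highlight_level": self.highlight_level,
            "dropped_rows": list(self.dropped_rows),
            "mi_scores": self.mi_scores,
        }


# ---------------------------------------------------------------------------
# normalisation


def normalise_axis(values: Sequence[float] | np.ndarray, method: str) -> np.ndarray:
    """Map a numeric vector (NaN = missing) onto [0,1]; NaN stays NaN.

    * ``minmax`` — linear, min -> 0, max -> 1.
    * ``rank`` — average ranks rescaled to equally spaced points in [0,1].
    * ``zscore`` — standardise, clip at +-3 sigma, rescale to [0,1].

    A constant column maps every observed value to 0.5 under every method.
    """
    if method not in NORMALISATIONS:
        raise ContractError(f"unknown normalisation {method!r}; choose from {NORMALISATIONS}")
    try:
        x = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ContractError(f"normalise_axis requires numeric input: {exc}") from exc
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    if not obs.any():
        return out
    xo = x[obs]
    if np.all(xo == xo[0]):
        out[obs] = 0.5
        return out
    if method == "minmax":
        lo, hi = xo.min(), xo.max()
        out[obs] = (xo - lo) / (hi - lo)
    elif method == "rank":
        r = rankdata(xo, method="average")
        out[obs] = (r - 1.0) / (len(xo) - 1.0)
    else:  # zscore, clipped at 3 sigma
        z = (xo - xo.mean()) / xo.std()
        out[obs] = (np.clip(z, -3.0, 3.0) + 3.0) / 6.0
    return out


# ---------------------------------------------------------------------------
# crossing counts


def _count_strict_inversions(seq: list[float]) -> int:
    """Pairs i<j with seq[i] > seq[j], by merge sort. Ties contribute zero."""
    n = len(seq)
    if n < 2:
        return 0
    mid = n // 2
    left, right = seq[:mid], seq[mid:]
    count = _count_strict_inversions(left) + _count_strict_inversions(right)
    merged: list[float] = []
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            # left[i] > right[j]: every remaining left element inverts with right[j]
            count += len(left) - i
            merged.append(right[j])
            j += 1
    merged.extend(left[i:])
    merged.extend(right[j:])
    seq[:] = merged
    return count


def count_crossings(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> int:
    """Number of polyline crossings between two adjacent axes.

    Equals the inversion count |{(i,j): i<j, (a_i-a_j)(b_i-b_j) < 0}| over
    the rows observed on both axes; tied pairs contribute nothing.
    O(n log n), contractually identical to the quadratic definition.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError(f"axis vectors must be 1-D and equal length: {a.shape} vs {b.shape}")
    complete = ~(np.isnan(a) | np.isnan(b))
    a, b = a[complete], b[complete]
    if a.size < 2:
        return 0
    # sort by a ascending, ties by b ascending: strict inversions in the
    # resulting b sequence are exactly the sign-reversed pairs
    order = np.lexsort((b, a))
    return _count_strict_inversions(list(b[order]))


def crossing_matrix(
    table: TypedTable, axes: Sequence[str], normalisation: str = "minmax"
) -> CrossingMatrix:
    """Pairwise crossing counts between the named numeric axes.

    Each pair is counted over its pairwise-complete rows after per-column
    normalisation; the result is symmetric with a zero diagonal.
    """
    for name in axes:
        if table.spec(name).role is not Role.NUMERIC:
            raise ContractError(f"axis {name!r} is not numeric")
    normed = {name: normalise_axis(table.values[name], normalisation) for name in axes}
    k = len(axes)
    counts = np.zeros((k, k), dtype=np.int64)
    for i, j in itertools.combinations(range(k), 2):
        c = count_crossings(normed[axes[i]], normed[axes[j]])
        counts[i, j] = counts[j, i] = c
    return CrossingMatrix(axes=tuple(axes), counts=counts)


# ---------------------------------------------------------------------------
# axis ordering: crossing minimisation


def _path_cost(counts: np.ndarray, order: Sequence[int]) -> int:
    return int(sum(counts[order[t], order[t + 1]] for t in range(len(order) - 1)))


def _two_opt(counts: np.ndarray, order: list[int]) -> list[int]:
    k = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                candidate = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                if _path_cost(counts, candidate) < _path_cost(counts, order):
                    order = candidate
                    improved = True
    return order


def order_axes_min_crossings(matrix: CrossingMatrix) -> list[str]:
    """Axis ordering minimising total crossings between adjacent axes.

    Open-path objective: sum of counts over consecutive pairs. Exact by
    exhaustive enumeration for k <= 8 axes; greedy nearest-neighbour from
    every start plus 2-opt otherwise (deterministic, never worse than the
    input order). Among equal-cost orderings the lexicographically smallest
    by original column index is returned, which also fixes the
    reversal-equivalence ambiguity (first index < last index).
    """
    k = len(matrix.axes)
    counts = matrix.counts
    if k == 1:
        return [matrix.axes[0]]
    if k <= EXACT_ORDERING_LIMIT:
        best: tuple[int, ...] | None = None
        best_cost = math.inf
        for perm in itertools.permutations(range(k)):
            cost = _path_cost(counts, perm)
            if cost < best_cost:
                best, best_cost = perm, cost
        assert best is not None
        return [matrix.axes[i] for i in best]
    # heuristic regime
    candidates: list[list[int]] = [list(range(k))]  # input order is always a candidate
    for start in range(k):
        path = [start]
        remaining = set(range(k)) - {start}
        while remaining:
            last = path[-1]
            nxt = min(remaining, key=lambda j: (counts[last, j], j))
            path.append(nxt)
            remaining.remove(nxt)
        candidates.append(path)
    best_order = min(candidates, key=lambda o: (_path_cost(counts, o), o))
    best_order = _two_opt(counts, best_order)
    if best_order[0] > best_order[-1]:
        best_order = best_order[::-1]
    return [matrix.axes[i] for i in best_order]


# ---------------------------------------------------------------------------
# mutual information


def default_n_bins(n: int) -> int:
    return min(10, max(2, math.ceil(math.sqrt(n))))


def _discrete_codes(labels: np.ndarray) -> np.ndarray:
    seen: dict[object, int] = {}
    codes = np.empty(len(labels), dtype=np.int64)
    for i, v in enumerate(labels):
        codes[i] = seen.setdefault(v, len(seen))
    return codes


def mutual_information(
    feature: Sequence[float] | np.ndarray,
    labels: Sequence[object] | np.ndarray,
    n_bins: int,
) -> float:
    """Plug-in mutual information (bits) between a binned numeric feature
    and a categorical label vector.

    The feature is discretised into ``n_bins`` equal-frequency bins
    (duplicate quantile edges merged, so the effective bin count may be
    smaller); the plug-in estimate sum p(x,y) log2(p(x,y)/(p(x)p(y))) is
    taken on the resulting contingency table. Rows missing on either side
    are excluded pairwise. Degenerate inputs (fewer than 2 usable rows, a
    single label level, or a constant feature) yield 0 with a warning.
    """
    if n_bins < 1:
        raise ContractError("n_bins must be positive")
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels, dtype=object)
    if x.shape != y.shape:
        raise ContractError("feature and labels must have equal length")
    usable = ~np.isnan(x) & np.array([v is not None for v in y])
    x, y = x[usable], y[usable]
    if len(x) < 2:
        logger.warning("mutual_information: fewer than 2 usable rows; returning 0")
        return 0.0
    codes = _discrete_codes(y)
    if codes.max() == 0:
        logger.warning("mutual_information: single label level; returning 0")
        return 0.0
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 3:  # constant feature or single effective bin
        return 0.0
    bins = np.searchsorted(edges[1:-1], x, side="right")
    n_x = int(bins.max()) + 1
    n_y = int(codes.max()) + 1
    joint = np.zeros((n_x, n_y))
    np.add.at(joint, (bins, codes), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def order_axes_by_mi(
    table: TypedTable,
    axes: Sequence[str],
    class_column: str,
    n_bins: int | None = None,
) -> list[tuple[str, float]]:
    """Axes sorted by mutual information with the class column, descending.

    Ties are broken by the original column order. Returns (column, bits)
    pairs so callers can log the score table.
    """
    cls = table.spec(class_column)
    if cls.role not in (Role.CATEGORICAL, Role.BOOLEAN):
        raise ContractError(f"class column {class_column!r} must be categorical or boolean")
    for name in axes:
        if table.spec(name).role is not Role.NUMERIC:
            raise ContractError(f"axis {name!r} is not numeric")
    labels = table.values[class_column]
    if n_bins is None:
        n_bins = default_n_bins(table.n_rows)
    scored = [(name, mutual_information(table.values[name], labels, n_bins)) for name in axes]
    # stable sort descending preserves original order among ties
    return sorted(scored, key=lambda t: -t[1])


# ---------------------------------------------------------------------------
# layout assembly


@dataclass(frozen=True)
class PcpOptions:
    axes: tuple[str, ...] | None = None
    colour_feature: str | None = None
    highlight_level: str | None = None
    ordering: str = "given"  # given | crossings | mi
    normalisation: str = "minmax"
    n_bins: int | None = None
    missing_policy: str = "drop_rows"  # drop_rows | drop_and_report


def build_pcp_layout(table: TypedTable, options: PcpOptions = PcpOptions()) -> PcpLayout:
    """Assemble PCP geometry from a TypedTable.

    Rows missing on any plotted axis are excluded and listed in
    ``dropped_rows``. Highlighted samples are foreground-styled; the rest of
    the cohort becomes background context.
    """
    if options.ordering not in ("given", "crossings", "mi"):
        raise ConfigError(f"unknown ordering strategy {options.ordering!r}")
    if options.missing_policy not in ("drop_rows", "drop_and_report"):
        raise ConfigError(f"unknown missing policy {options.missing_policy!r}")
    axes = list(options.axes) if options.axes else table.numeric_columns()
    for name in axes:
        if name not in table.column_names:
            raise ConfigError(f"axis {name!r} not found in table")
        if table.spec(name).role is not Role.NUMERIC:
            raise ConfigError(f"axis {name!r} is not numeric")
    if len(axes) < 2:
        raise InputFormatError(
            f"parallel coordinates need at least 2 numeric axes, found {len(axes)}"
        )
    colour = options.colour_feature
    if colour is not None and colour not in table.column_names:
        raise ConfigError(f"colour feature {colour!r} not found in table")
    if options.highlight_level is not None:
        if colour is None:
            raise ConfigError("highlight_level requires colour_feature")
        cspec = table.spec(colour)
        if cspec.is_discrete and options.highlight_level not in cspec.levels:
            raise ConfigError(
                f"highlight level {options.highlight_level!r} not among levels of "
                f"{colour!r}: {', '.join(cspec.levels)}"
            )

    # ordering strategy
    if options.ordering == "crossings":
        ordered = order_axes_min_crossings(crossing_matrix(table, axes, options.normalisation))
        mi_scores = None
    elif options.ordering == "mi":
        if colour is None:
            raise ConfigError("ordering='mi' requires a colour feature (class column)")
        scored = order_axes_by_mi(table, axes, colour, options.n_bins)
        ordered = [name for name, _ in scored]
        mi_scores = {name: score for name, score in scored}
    else:
        ordered = axes
        mi_scores = None

    # drop rows incomplete on any plotted axis
    axis_missing = np.column_stack([table.column_missing(name) for name in ordered])
    incomplete = axis_missing.any(axis=1)
    dropped_rows = [int(i) for i in np.flatnonzero(incomplete)]
    kept = np.flatnonzero(~incomplete)
    if options.missing_policy == "drop_and_report":
        for t, name in enumerate(ordered):
            logger.info("axis %s: %d missing value(s)", name, int(axis_missing[:, t].sum()))
    if dropped_rows:
        logger.info("dropped %d row(s) incomplete on plotted axes", len(dropped_rows))

    heights = {
        name: normalise_axis(table.values[name][kept], options.normalisation) for name in ordered
    }
    colour_vals = None
    if colour is not None:
        cvec = table.values[colour]
        colour_vals = [None if cvec[i] is None else str(cvec[i]) for i in kept]

    polylines: list[PolyLine] = []
    for pos, i in enumerate(kept):
        cval = colour_vals[pos] if colour_vals is not None else None
        fg = True if options.highlight_level is None else (cval == options.highlight_level)
        polylines.append(
            PolyLine(
                row=int(i),
                heights=tuple(float(heights[name][pos]) for name in ordered),
                foreground=fg,
                colour_value=cval,
            )
        )
    axis_specs = [
        AxisSpec(column=name, normalisation=options.normalisation, position=t)
        for t, name in enumerate(ordered)
    ]
    return PcpLayout(
        axes=axis_specs,
        polylines=polylines,
        colour_feature=colour,
        highlight_level=options.highlight_level,
        dropped_rows=dropped_rows,
        mi_scores=mi_scores,
    )
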