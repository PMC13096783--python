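"""Tiled one-dimensional stacked-plot layout engine.

One vertically aligned track per feature — colour tiles for categorical /
boolean columns, bars for numeric ones — sharing a single sample order, so
cross-feature patterns read as vertical alignment. Missing cells are marked
with explicit "!" glyphs, making missingness a first-class visual signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import ConfigError, ContractError, InputFormatError
from .table_model import ColumnSpec, Role, TypedTable

__all__ = [
    "QUALITATIVE_PALETTE",
    "TrackSpec",
    "GlyphMark",
    "TiledLayout",
    "TileOptions",
    "select_track_type",
    "palette_for_levels",
    "order_samples",
    "build_tiled_layout",
]

logger = logging.getLogger(__name__)

# colour-blind-aware qualitative cycle (12 entries, cycled beyond that)
QUALITATIVE_PALETTE: tuple[str, ...] = (
    "#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE", "#AA3377",
    "#BBBBBB", "#E69F00", "#56B4E9", "#009E73", "#D55E00", "#CC79A7",
)

BAR_COLOUR = "#4477AA"
MISSING_TILE_COLOUR = "#EBEBEB"

DEFAULT_MAX_ROWS_WARN = 1000


@dataclass(frozen=True)
class TrackSpec:
    """One feature's row in the stacked layout: a tile or bar track."""

    column: str
    kind: str  # "tile" | "bar"
    palette: dict | str = BAR_COLOUR
    height_scale: tuple[float, float] | None = None  # bar tracks only: (min, max)


@dataclass(frozen=True)
class GlyphMark:
    row: int
    track: str
    glyph: str = "!"


@dataclass
class TiledLayout:
    """Renderable stacked-track geometry.

    ``cells[column]`` holds one record per original row index: a level
    string (tile), a bar height in [0,1] (bar), or None where the value is
    missing. ``sample_order`` is the display permutation of row indices.
    """

    sample_order: list[int]
    tracks: list[TrackSpec]
    cells: dict[str, list]
    glyphs: list[GlyphMark]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.sample_order)

    def to_dict(self) -> dict:
        return {
            "kind": "tiled",
            "sample_order": list(self.sample_order),
            "tracks": [
                {
                    "column": t.column,
                    "kind": t.kind,
                    "palette": t.palette,
                    "height_scale": list(t.height_scale) if t.height_scale else None,
                }
                for t in self.tracks
            ],
            "cells": {k: list(v) for k, v in self.cells.items()},
            "glyphs": [{"row": g.row, "track": g.track, "glyph": g.glyph} for g in self.glyphs],
            "warnings": list(self.warnings),
        }


def select_track_type(spec: ColumnSpec) -> str:
    """numeric -> bar; categorical/boolean -> tile; other roles are not tracks."""
    if spec.role is Role.NUMERIC:
        return "bar"
    if spec.role in (Role.CATEGORICAL, Role.BOOLEAN):
        return "tile"
    raise ContractError(f"column {spec.name!r} with role {spec.role.value} is not plottable as a track")


def palette_for_levels(levels: Sequence[str]) -> dict[str, str]:
    """Deterministic level->colour map on the fixed qualitative cycle."""
    return {lvl: QUALITATIVE_PALETTE[i % len(QUALITATIVE_PALETTE)] for i, lvl in enumerate(levels)}


# ---------------------------------------------------------------------------
# sample ordering


def order_samples(
    table: TypedTable, sort_keys: Sequence[tuple[str, str]] = ()
) -> list[int]:
    """Stable lexicographic multi-key row permutation.

    Categorical keys sort by level order, numeric by value; missing values
    always sort last within each key regardless of direction. An empty key
    list yields the identity permutation.
    """
    idx = list(range(table.n_rows))
    for column, direction in reversed(list(sort_keys)):
        if column not in table.column_names:
            raise ConfigError(f"sort key {column!r} not found in table")
        if direction not in ("asc", "desc"):
            raise ConfigError(f"sort direction must be asc|desc, got {direction!r}")
        spec = table.spec(column)
        vec = table.values[column]
        mask = table.column_missing(column)
        if spec.role is Role.NUMERIC:
            keyvals = [0.0 if mask[i] else float(vec[i]) for i in range(len(vec))]
        elif spec.is_discrete:
            rank = {lvl: r for r, lvl in enumerate(spec.levels)}
            keyvals = [0 if mask[i] else rank[vec[i]] for i in range(len(vec))]
        else:  # identifier / tooltip columns sort lexically by string
            keyvals = ["" if mask[i] else str(vec[i]) for i in range(len(vec))]
        # two stable passes: order by value (direction-aware), then push
        # missing rows last without disturbing relative order
        idx.sort(key=lambda i: keyvals[i], reverse=(direction == "desc"))
        idx.sort(key=lambda i: bool(mask[i]))
    return idx


# ---------------------------------------------------------------------------
# layout assembly


@dataclass(frozen=True)
class TileOptions:
    tracks: tuple[str, ...] | None = None
    sort_keys: tuple[tuple[str, str], ...] = ()
    palettes: dict | None = None  # column -> {level: colour} overrides
    max_rows_warn: int = DEFAULT_MAX_ROWS_WARN


def build_tiled_layout(table: TypedTable, options: TileOptions = TileOptions()) -> TiledLayout:
    """Assemble the stacked-track geometry for a TypedTable.

    Bar cells are minmax-normalised per track (constant tracks sit at 0.5);
    tile cells carry their level; every missing cell gets a GlyphMark. When
    n_rows >= max_rows_warn a size warning is appended (never a refusal).
    """
    if options.tracks is not None:
        track_cols = list(options.tracks)
        for name in track_cols:
            if name not in table.column_names:
                raise ConfigError(f"track {name!r} not found in table")
    else:
        track_cols = [
            c.name
            for c in table.columns
            if c.role in (Role.NUMERIC, Role.CATEGORICAL, Role.BOOLEAN)
        ]
    if not track_cols:
        raise InputFormatError("no plottable columns for a tiled layout")

    sample_order = order_samples(table, options.sort_keys)
    palettes = options.palettes or {}

    tracks: list[TrackSpec] = []
    cells: dict[str, list] = {}
    glyphs: list[GlyphMark] = []
    for name in track_cols:
        spec = table.spec(name)
        kind = select_track_type(spec)
        vec = table.values[name]
        mask = table.column_missing(name)
        if kind == "bar":
            observed = vec[~mask].astype(float)
            if observed.size == 0:
                lo = hi = 0.0
            else:
                lo, hi = float(observed.min()), float(observed.max())
            track_cells: list = []
            for i in range(table.n_rows):
                if mask[i]:
                    track_cells.append(None)
                elif hi == lo:
                    track_cells.append(0.5)
                else:
                    track_cells.append((float(vec[i]) - lo) / (hi - lo))
            tracks.append(
                TrackSpec(column=name, kind="bar", palette=BAR_COLOUR, height_scale=(lo, hi))
            )
        else:
            track_cells = [None if mask[i] else str(vec[i]) for i in range(table.n_rows)]
            palette = palettes.get(name) or palette_for_levels(spec.levels)
            tracks.append(TrackSpec(column=name, kind="tile", palette=palette))
        cells[name] = track_cells
        for i in np.flatnonzero(mask):
            glyphs.append(GlyphMark(row=int(i), track=name))

    warnings: list[str] = []
    if table.n_rows >= options.max_rows_warn:
        msg = (
            f"dataset has {table.n_rows} rows (>= {options.max_rows_warn}); tiled "
            "one-dimensional graphics are intended for smaller datasets (n < 1000) — "
            "consider a parallel coordinate plot instead"
        )
        warnings.append(msg)
        logger.warning(msg)
    logger.info("tiled layout: %d tracks, %d glyphs", len(tracks), len(glyphs))
    return TiledLayout(
        sample_order=sample_order,
        tracks=tracks,
        cells=cells,
        glyphs=glyphs,
        warnings=warnings,
    )
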