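"""Deterministic renderers for PCP and tiled layouts.

Two output surfaces, one geometry: ``render_svg`` emits a static SVG 1.1
document and ``render_html`` wraps the *same* SVG geometry in a
self-contained HTML page (no network fetches) with hover tooltips. Element
counts are exactly determined by the layout — one ``<path class="polyline">``
per sample line, one ``<rect class="cell">`` per cell, one
``<text class="glyph">`` per missing-value glyph — which is the test surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from xml.sax.saxutils import escape

from ._errors import ContractError
from .pcp_engine import PcpLayout
from .table_model import Role, TypedTable
from .tile_engine import MISSING_TILE_COLOUR, TiledLayout

__all__ = ["RenderOptions", "render_svg", "render_html"]

logger = logging.getLogger(__name__)

_THEMES = {
    "light": {"bg": "#FFFFFF", "fg": "#222222", "axis": "#888888", "line": "#4477AA"},
    "dark": {"bg": "#1E1E1E", "fg": "#EEEEEE", "axis": "#777777", "line": "#66CCEE"},
}

_HIGHLIGHT_COLOUR = "#EE6677"


@dataclass(frozen=True)
class RenderOptions:
    width: int = 900
    height: int = 520
    theme: str = "light"
    tooltip_columns: tuple[str, ...] = ()
    background_opacity: float = 0.25
    output_kind: str = "svg"  # svg | html

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ContractError("render dimensions must be positive")
        if self.theme not in _THEMES:
            raise ContractError(f"unknown theme {self.theme!r}")
        if not (0.0 <= self.background_opacity <= 1.0):
            raise ContractError("background_opacity must lie in [0,1]")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# PCP geometry


def _pcp_svg_body(layout: PcpLayout, options: RenderOptions, interactive: bool) -> list[str]:
    theme = _THEMES[options.theme]
    k = len(layout.axes)
    if k == 0:
        raise ContractError("cannot render a PCP layout with zero axes")
    margin_x, margin_top, margin_bottom = 60.0, 40.0, 50.0
    plot_w = options.width - 2 * margin_x
    plot_h = options.height - margin_top - margin_bottom
    xs = [margin_x + (plot_w * t / (k - 1) if k > 1 else plot_w / 2) for t in range(k)]

    parts: list[str] = []
    parts.append(
        f'<rect class="canvas" x="0" y="0" width="{options.width}" height="{options.height}" '
        f'fill="{theme["bg"]}"/>'
    )
    for t, axis in enumerate(layout.axes):
        x = _fmt(xs[t])
        parts.append(
            f'<line class="axis" x1="{x}" y1="{_fmt(margin_top)}" x2="{x}" '
            f'y2="{_fmt(margin_top + plot_h)}" stroke="{theme["axis"]}" stroke-width="1"/>'
        )
        parts.append(
            f'<text class="axis-label" x="{x}" y="{_fmt(margin_top + plot_h + 20)}" '
            f'fill="{theme["fg"]}" font-size="12" text-anchor="middle">'
            f"{escape(axis.column)}</text>"
        )
    if not layout.polylines:
        logger.warning("PCP layout has no polylines (all rows dropped)")

    def path_for(poly) -> str:
        pts = [
            f"{_fmt(xs[t])},{_fmt(margin_top + (1.0 - h) * plot_h)}"
            for t, h in enumerate(poly.heights)
        ]
        d = "M " + " L ".join(pts)
        if poly.foreground:
            colour = _HIGHLIGHT_COLOUR if layout.highlight_level is not None else theme["line"]
            opacity = 0.85
        else:
            colour, opacity = theme["axis"], options.background_opacity
        data_attr = f' data-row="{poly.row}"' if interactive else ""
        return (
            f'<path class="polyline" d="{d}" fill="none" stroke="{colour}" '
            f'stroke-width="1.2" stroke-opacity="{opacity}"{data_attr}/>'
        )

    # background lines first so highlighted samples sit on top (z-order)
    for poly in layout.polylines:
        if not poly.foreground:
            parts.append(path_for(poly))
    for poly in layout.polylines:
        if poly.foreground:
            parts.append(path_for(poly))
    return parts


# ---------------------------------------------------------------------------
# tiled geometry


def _tiled_svg_body(layout: TiledLayout, options: RenderOptions, interactive: bool) -> list[str]:
    theme = _THEMES[options.theme]
    if not layout.tracks:
        raise ContractError("cannot render a tiled layout with zero tracks")
    n = layout.n_rows
    margin_left, margin_right, margin_top, margin_bottom = 120.0, 20.0, 20.0, 20.0
    plot_w = options.width - margin_left - margin_right
    plot_h = options.height - margin_top - margin_bottom
    track_h = plot_h / len(layout.tracks)
    cell_w = plot_w / max(n, 1)
    pad = min(2.0, track_h * 0.08)

    parts: list[str] = []
    parts.append(
        f'<rect class="canvas" x="0" y="0" width="{options.width}" height="{options.height}" '
        f'fill="{theme["bg"]}"/>'
    )
    # display column for each original row index
    display_pos = {row: pos for pos, row in enumerate(layout.sample_order)}
    for ti, track in enumerate(layout.tracks):
        y0 = margin_top + ti * track_h
        parts.append(
            f'<text class="track-label" x="{_fmt(margin_left - 8)}" '
            f'y="{_fmt(y0 + track_h / 2 + 4)}" fill="{theme["fg"]}" font-size="12" '
            f'text-anchor="end">{escape(track.column)}</text>'
        )
        cells = layout.cells[track.column]
        for row, value in enumerate(cells):
            pos = display_pos[row]
            x = margin_left + pos * cell_w
            data_attr = f' data-row="{row}" data-track="{escape(track.column)}"' if interactive else ""
            if value is None:
                parts.append(
                    f'<rect class="cell" x="{_fmt(x)}" y="{_fmt(y0 + pad)}" '
                    f'width="{_fmt(max(cell_w - 0.5, 0.1))}" height="{_fmt(track_h - 2 * pad)}" '
                    f'fill="{MISSING_TILE_COLOUR}"{data_attr}/>'
                )
            elif track.kind == "bar":
                bar_h = max(float(value) * (track_h - 2 * pad), 0.0)
                parts.append(
                    f'<rect class="cell" x="{_fmt(x)}" y="{_fmt(y0 + track_h - pad - bar_h)}" '
                    f'width="{_fmt(max(cell_w - 0.5, 0.1))}" height="{_fmt(bar_h)}" '
                    f'fill="{track.palette}"{data_attr}/>'
                )
            else:
                colour = track.palette.get(str(value), MISSING_TILE_COLOUR)
                parts.append(
                    f'<rect class="cell" x="{_fmt(x)}" y="{_fmt(y0 + pad)}" '
                    f'width="{_fmt(max(cell_w - 0.5, 0.1))}" height="{_fmt(track_h - 2 * pad)}" '
                    f'fill="{colour}"{data_attr}/>'
                )
    glyph_size = min(track_h * 0.7, 14.0)
    for g in layout.glyphs:
        ti = next(i for i, t in enumerate(layout.tracks) if t.column == g.track)
        y0 = margin_top + ti * track_h
        x = margin_left + display_pos[g.row] * cell_w + cell_w / 2
        parts.append(
            f'<text class="glyph" x="{_fmt(x)}" y="{_fmt(y0 + track_h / 2 + glyph_size / 3)}" '
            f'fill="{theme["fg"]}" font-size="{_fmt(glyph_size)}" font-weight="bold" '
            f'text-anchor="middle">{escape(g.glyph)}</text>'
        )
    return parts


# ---------------------------------------------------------------------------
# public renderers


def _svg_document(layout, options: RenderOptions, interactive: bool) -> str:
    if isinstance(layout, PcpLayout):
        body = _pcp_svg_body(layout, options, interactive)
    elif isinstance(layout, TiledLayout):
        body = _tiled_svg_body(layout, options, interactive)
    else:
        raise ContractError(f"cannot render layout of type {type(layout).__name__}")
    header = (
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{options.width}" height="{options.height}" '
        f'viewBox="0 0 {options.width} {options.height}">'
    )
    return "\n".join([header, *body, "</svg>"]) + "\n"


def render_svg(layout: PcpLayout | TiledLayout, options: RenderOptions = RenderOptions()) -> str:
    """Render a layout to SVG text. Identical inputs give identical bytes."""
    return _svg_document(layout, options, interactive=False)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>edalayout</title>
<style>
body {{ margin: 0; font-family: sans-serif; background: {bg}; }}
#tooltip {{
  position: fixed; display: none; pointer-events: none;
  background: rgba(20,20,20,0.92); color: #fff; padding: 6px 9px;
  border-radius: 4px; font-size: 12px; white-space: pre; z-index: 10;
}}
.polyline:hover {{ stroke-width: 3; stroke-opacity: 1; }}
.cell:hover {{ stroke: #000; stroke-width: 1; }}
</style>
</head>
<body>
{svg}
<div id="tooltip"></div>
<script>
var TIPS = {tips_json};
var tip = document.getElementById("tooltip");
function show(evt, row) {{
  var lines = ["sample " + row];
  var extra = TIPS[row] || [];
  for (var i = 0; i < extra.length; i++) lines.push(extra[i]);
  tip.textContent = lines.join("\\n");
  tip.style.left = (evt.clientX + 12) + "px";
  tip.style.top = (evt.clientY + 12) + "px";
  tip.style.display = "block";
}}
function hide() {{ tip.style.display = "none"; }}
var hoverables = document.querySelectorAll("[data-row]");
for (var i = 0; i < hoverables.length; i++) {{
  var el = hoverables[i];
  el.addEventListener("mousemove", function (evt) {{
    show(evt, this.getAttribute("data-row"));
  }});
  el.addEventListener("mouseleave", hide);
}}
</script>
</body>
</html>
"""


def render_html(
    layout: PcpLayout | TiledLayout,
    options: RenderOptions = RenderOptions(),
    source: TypedTable | None = None,
) -> str:
    """Render a layout to a single self-contained HTML document.

    Hovering a polyline or cell shows the sample index plus the values of
    ``options.tooltip_columns`` drawn from ``source``. The plotted geometry
    is identical to :func:`render_svg`'s.
    """
    tips: dict[int, list[str]] = {}
    if source is not None and options.tooltip_columns:
        for name in options.tooltip_columns:
            if name not in source.column_names:
                raise ContractError(f"tooltip column {name!r} not found in source table")
        for i in range(source.n_rows):
            lines = []
            for name in options.tooltip_columns:
                if source.missing_mask[i, source.column_index(name)]:
                    val = "(missing)"
                elif source.spec(name).role is Role.NUMERIC:
                    val = repr(float(source.values[name][i]))
                else:
                    val = str(source.values[name][i])
                lines.append(f"{name}: {val}")
            tips[i] = lines
    svg = _svg_document(layout, options, interactive=True)
    theme = _THEMES[options.theme]
    return _HTML_TEMPLATE.format(
        bg=theme["bg"],
        svg=svg,
        tips_json=json.dumps({str(k): v for k, v in tips.items()}, sort_keys=True),
    )
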