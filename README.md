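# edalayout

Layout engines for exploratory data analysis graphics, built geometry-first
so every plot is testable without touching pixels. Two complementary views
of rectangular cohort data:

* **Parallel coordinate plots** (`parallel`) — every numeric feature becomes
  a vertical axis and every sample a polyline. Axes can be reordered by
  *crossing minimisation* (exact for ≤ 8 axes, greedy + 2-opt above) or by
  *mutual information* with a categorical class feature; a single subclass
  can be highlighted against the backgrounded cohort.
* **Tiled one-dimensional graphics** (`tiles`) — one vertically aligned
  track per feature (colour tiles for categorical/boolean columns, bars for
  numeric ones) sharing a single sample order, with explicit `!` glyphs
  wherever a value is missing. Multidimensional missingness patterns read
  as vertical alignment. Intended for smaller datasets (a warning fires at
  n ≥ 1000, but rendering proceeds).

Both commands read plain CSV/TSV (header row, empty cells = missing) and
write either a deterministic static SVG or a self-contained interactive
HTML document with hover tooltips — chosen by the output file extension.

## CLI

```sh
# generate a demo dataset whose count column goes missing exactly when the
# lazy observer was on duty on a weekend
edalayout synth lazy-birdwatcher --n 120 --seed 1 --out birds.csv

# tiled stacked tracks; the missingness pattern appears as aligned "!" glyphs
edalayout tiles -i birds.csv -o birds.html --sort-by Birdwatcher --sort-by Day

# parallel coordinates with crossing-minimised axis order
edalayout synth correlated --n 300 --seed 1 --columns 6 --rho 0.7 --out beansish.csv
edalayout parallel -i beansish.csv -o beansish.svg --order crossings

# mutual-information axis ordering + subclass highlighting
edalayout synth class-mixture --n 500 --seed 1 --out mix.csv
edalayout parallel -i mix.csv -o mix.html --order mi --colour class \
    --highlight class_0 --tooltip class
```

Shared flags: `--input/-i`, `--output/-o`, `--config` (YAML; CLI flags
override config values, config overrides built-in defaults), `--na-token`
(repeatable), `--max-levels`, `--verbose/-v`. Exit codes: 0 success, 2
input/format error, 3 configuration error. Logs go to stderr.

Column roles are inferred automatically (numbers → numeric, true/false →
boolean, everything else → categorical; integer columns with ≤ 5 distinct
values are treated as categorical codes) and can be overridden via the
library API.

## Library

```python
from edalayout import (
    read_table, build_pcp_layout, build_tiled_layout,
    PcpOptions, TileOptions, render_svg, render_html,
)

table = read_table("birds.csv")
layout = build_tiled_layout(table, TileOptions(sort_keys=(("Birdwatcher", "asc"), ("Day", "asc"))))
open("birds.svg", "w").write(render_svg(layout))
```

`build_pcp_layout` / `build_tiled_layout` return plain geometry objects
(`PcpLayout`, `TiledLayout`) with `to_dict()` serialisations; the renderers
consume the same geometry, so element counts in the SVG/HTML are exactly
determined by the layout.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains per-module unit tests, hypothesis property tests
(inversion counting vs a quadratic oracle, normalisation invariants,
type-inference rules), and `tests/test_acceptance.py`, one test per
acceptance criterion.

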