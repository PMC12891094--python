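# progmat

Rule-based generation of Raven-like progressive-matrix items: 2×2 / 3×3
matrices built from tagged vector figures and transformation rules, with an
automatically generated 11-option response list (the correct response plus
ten theory-grounded distractors) and SVG/PNG rendering.

## What it does

- **Figures** (`progmat.figures`): every drawable element is a 15-field
  feature record (shape, ellipse axes, arc angles, rotation, position, line
  type/width, draw mode, vertex count, fill, visibility, tags). A primitive
  registry (square, circle, dot, ellipse, triangle, pentagon, hexagon,
  lines, a four-line square `square4`, a four-petal flower `miley`, a malta
  cross, …) is extensible at run time. `cof()` concatenates figures,
  optionally forcing the result to count as a single figure.
- **Rules** (`progmat.rules`): identity; incremental size (k = 0.9 forward,
  0.6 reverse) and rotation (θ = π/X, default π/4); permutational line
  width/type, shade (white → gray → black), multi-shade and shape
  permutation; logical AND/OR/XOR rules realized row- or column-wise from a
  seeded partition of the figure's elements into sets A, B, C.
- **Matrices** (`progmat.matrices`): `mat_apply(start, hrules, vrules,
  mat_type, seed)` builds a matrix (horizontal rules iterate over columns,
  vertical over rows; transformations accumulate), `com()` layers matrices
  background-to-foreground, `classify_direction()` reports H / V / TL-LR /
  LL-TR logic per rule.
- **Responses** (`progmat.responses`): `response_list(matrix, seed)` returns
  the 11 named options — `correct, r_diag, r_left, r_top, wp_copy,
  wp_matrix, difference, ic_neg, ic_flip, ic_size, ic_inc`. Infeasible or
  degenerate options are replaced by the correct response under a thick
  black cross, with a warning recorded.
- **Rendering** (`progmat.render`): `draw()` for figures, matrices (blank
  last cell) and response lists (full, labeled, or named subsets);
  `export()` / `export_split()` write deterministic SVG or PNG.
- **Fixtures** (`progmat.fixtures`): seeded streams of valid item specs for
  property testing, plus known-degenerate edge cases and the worked
  two-layer AND/OR logic example (`tutorial_item()`).

## Library example

```python
import progmat as pm

triple = pm.cof(pm.make_primitive("hexagon"), pm.make_primitive("pentagon"),
                pm.make_primitive("square"))
matrix = pm.mat_apply(triple, hrules=["shape"], vrules=["shade"])
options = pm.response_list(matrix, seed=3)
pm.export(matrix, "item_matrix.svg")
pm.export(options, "item_options.svg", show_labels=True)
```

## CLI

```sh
progmat generate --config config.yaml --out out/ [--seed N] [--format svg|png] [--split]
progmat validate --spec item.json
```

`config.yaml` holds either an `items:` list of item specs
(`start` figure(s) per layer, `hrules`/`vrules` per layer, `mat_type`,
`seed`) or a `fixture:` block for randomized generation. `generate` writes
one matrix image and 11 option images per item, a `manifest.json` and a
Markdown contact sheet; `validate` dry-runs precondition checks and prints a
JSON violation report.

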