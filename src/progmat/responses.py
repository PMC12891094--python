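"""Response-list generation: the correct response plus ten distractors.

The generator returns an ordered, named list of 11 options: the correct
response, three Repetition options (copies of cells adjacent to the blank),
two Wrong-Principle options (copy/recombination of a non-adjacent cell), one
Difference option (matrix content merged with a figure foreign to the
matrix) and four Incomplete-Correlate options (single-feature modifications
of the correct response: fill inversion, flip/rotation, resize, element
removal).

Any option that cannot be generated, or that turns out equal to the correct
response, is replaced by the correct response covered by a thick black cross
and a warning is recorded.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError
from .figures import (
    Element,
    Figure,
    cof,
    figure_to_dict,
    figures_equal,
    invert_fill,
    list_primitives,
    make_primitive,
    mirror_figure,
    rotate_figure,
    scale_figure,
)
from .matrices import Matrix, classify_direction, correct_response, n_rules
from .rules import LOGICAL_RULES

__all__ = [
    "OPTION_NAMES",
    "IC_INC_SINGLE_WARNING",
    "ResponseList",
    "crossed_out",
    "gen_difference",
    "gen_incomplete_correlates",
    "gen_wrong_principle",
    "is_crossed",
    "response_list",
    "response_list_to_dict",
    "select_source_cell",
]

#: the 11 option names, in canonical order
OPTION_NAMES = (
    "correct", "r_diag", "r_left", "r_top", "wp_copy", "wp_matrix",
    "difference", "ic_neg", "ic_flip", "ic_size", "ic_inc",
)

IC_INC_SINGLE_WARNING = "IC-Inc cannot be obtained with a single figure"

#: ic_size shrink factor applied to the resized layer
IC_SIZE_FACTOR = 0.5

_CROSS_TAG = "cross.out"


@dataclass(frozen=True)
class ResponseList:
    """Ordered named options (always 11) plus warning records."""

    options: dict[str, Figure]
    warnings: tuple[tuple[str, str], ...]
    seed: int

    def __post_init__(self) -> None:
        if tuple(self.options) != OPTION_NAMES:
            raise ValidationError(
                f"options must be exactly {OPTION_NAMES}, got {tuple(self.options)}")

    def names(self) -> list[str]:
        return list(self.options)

    def __getitem__(self, name: str) -> Figure:
        return self.options[name]

    @property
    def crossed(self) -> list[str]:
        """Names of options replaced by the crossed-out fallback."""
        return [n for n, f in self.options.items() if is_crossed(f)]


def crossed_out(fig: Figure) -> Figure:
    """Overlay a figure with a thick black full-panel cross."""
    half = 20.0
    diag = half * math.sqrt(2.0)
    bar1 = Element(shape=_CROSS_TAG, nv=2, size_y=diag, rotation=math.pi / 4,
                   lwd=3, tag=frozenset({_CROSS_TAG}))
    bar2 = bar1.replace(rotation=-math.pi / 4)
    cross = Figure((bar1, bar2), (_CROSS_TAG,), ((0, 1),))
    return cof(fig, cross)


def is_crossed(fig: Figure) -> bool:
    return any(e.shape == _CROSS_TAG for e in fig.elements)


# ---------------------------------------------------------------------------
# source-cell selection for WP and D distractors
# ---------------------------------------------------------------------------

def select_source_cell(m: Matrix, purpose: str = "wp") -> str:
    """Cell used as WP/D source material.

    3x3: ``Sq1`` for a single rule manipulated with H, V or TL-LR logic;
    ``Sq3`` for a single LL-TR rule or when two or more rules are
    manipulated (this keeps WP-Copy from reading as an IC option).
    2x2: ``Sq3`` when at least one rule is applied both horizontally and
    vertically; otherwise ``Sq2`` for WP-Matrix and ``Sq1`` for Difference.
    """
    dirs = classify_direction(m)
    if m.mat_type == 9:
        if len(dirs) <= 1 and all(d in ("H", "V", "TL-LR") for d in dirs.values()):
            return "Sq1"
        return "Sq3"
    both = any(d in ("TL-LR", "LL-TR", "mixed") for d in dirs.values())
    if both:
        return "Sq3"
    return "Sq2" if purpose == "wp" else "Sq1"


# ---------------------------------------------------------------------------
# distractor families
# ---------------------------------------------------------------------------

def gen_wrong_principle(m: Matrix, source: str | None = None) -> tuple[Figure, Figure]:
    """(wp_copy, wp_matrix): a non-adjacent cell and its recombination.

    wp_copy is the source cell verbatim.  wp_matrix superimposes another
    cell on the source (3x3) or the quarter-turn of wp_copy on the
    Sq3/Sq2 base cell (2x2).
    """
    if m.mat_type == 9:
        src = source or select_source_cell(m, "wp")
        wp_copy = m.cells[src]
        wp_matrix = cof(m.cells[src], m.cells["Sq2"])
    else:
        wp_copy = m.cells["Sq1"]
        base = source or select_source_cell(m, "wp")
        wp_matrix = cof(m.cells[base], rotate_figure(wp_copy, math.pi / 2))
    return wp_copy, wp_matrix


def _names_in_matrix(m: Matrix) -> set:
    used: set = set()
    for fig in m.cells.values():
        used.update(fig.names)
        used.update(e.shape for e in fig.elements)
    return used


def gen_difference(m: Matrix, source: str | None = None,
                   seed: int = 0) -> tuple[Figure | None, str | None]:
    """Difference option: merged matrix cells plus a foreign figure.

    The merge uses {source, Sq4, Sq7} for 3x3 matrices and the single source
    cell for 2x2.  The superimposed figure is drawn (seeded) from the
    registry restricted to ``d.ext``/``d.int``-tagged primitives whose names
    occur nowhere in the matrix.  Returns ``(figure, None)`` or
    ``(None, warning)`` when no foreign figure is available.
    """
    src = source or select_source_cell(m, "difference")
    parts = [m.cells[src]] + ([m.cells["Sq4"], m.cells["Sq7"]] if m.mat_type == 9 else [])
    merged = cof(*parts)
    used = _names_in_matrix(m)
    pool = sorted(set(list_primitives("d.ext")) | set(list_primitives("d.int")))
    candidates = [p for p in pool if p not in used]
    if not candidates:
        return None, "Difference cannot be obtained: no figure foreign to the matrix is available"
    rng = random.Random(f"difference:{seed}")
    foreign = make_primitive(rng.choice(candidates))
    return cof(merged, foreign), None


def _layer_slices(m: Matrix) -> list[range]:
    out, offset = [], 0
    for size in m.layer_sizes:
        out.append(range(offset, offset + size))
        offset += size
    return out


def _layer_tags(fig: Figure, sl: range) -> frozenset:
    tags: frozenset = frozenset()
    for i in sl:
        tags |= fig.elements[i].tag
    return tags


def _find_layer(fig: Figure, slices: list[range], required: str) -> range | None:
    """Foreground-most layer whose tags include ``required``."""
    for sl in reversed(slices):
        if required in _layer_tags(fig, sl):
            return sl
    return None


def gen_incomplete_correlates(m: Matrix, seed: int = 0) -> tuple[dict, list]:
    """The four IC options, each a single-feature modification of the
    correct response, applied to the foreground-most layer whose tags allow
    the manipulation.

    Returns ``(options, warnings)`` where infeasible options map to ``None``
    and carry a warning message.
    """
    correct = correct_response(m)
    slices = _layer_slices(m)
    warnings: list[tuple[str, str]] = []
    out: dict[str, Figure | None] = {}

    # ic_neg: fill inversion -- needs a fill-capable layer
    sl = _find_layer(correct, slices, "fill")
    if sl is None:
        out["ic_neg"] = None
        warnings.append(("ic_neg",
                         "IC-Neg cannot be obtained: the filling color cannot be changed"))
    else:
        out["ic_neg"] = invert_fill(correct, sl)

    # ic_flip: rotation when a rotatable layer exists, else a mirror flip
    sl = _find_layer(correct, slices, "rotate")
    if sl is not None:
        out["ic_flip"] = rotate_figure(correct, math.pi / 2, sl)
    else:
        out["ic_flip"] = mirror_figure(correct, slices[-1])

    # ic_size: only the most internal (foreground) layer is resized
    out["ic_size"] = scale_figure(correct, IC_SIZE_FACTOR, slices[-1])

    # ic_inc: removal of an element -- impossible with a single figure
    if m.n_layers < 2:
        out["ic_inc"] = None
        warnings.append(("ic_inc", IC_INC_SINGLE_WARNING))
    else:
        logical = any(name in LOGICAL_RULES
                      for h, v in m.layer_rules for name in tuple(h) + tuple(v))
        if logical:
            # logic matrices: the removed element is randomly selected
            rng = random.Random(f"ic_inc:{seed}")
            visible = [i for i, e in enumerate(correct.elements) if e.visible >= 1]
            drop = {rng.choice(visible)} if visible else set()
        else:
            drop = set(slices[-1])  # the foreground figure is removed
        kept = [i for i in range(len(correct.elements)) if i not in drop]
        elements = tuple(correct.elements[i] for i in kept)
        remap = {old: new for new, old in enumerate(kept)}
        names, groups = [], []
        for name, grp in zip(correct.names, correct.groups):
            g = tuple(remap[i] for i in grp if i in remap)
            if g:
                names.append(name)
                groups.append(g)
        out["ic_inc"] = Figure(elements, tuple(names), tuple(groups))

    return out, warnings


# ---------------------------------------------------------------------------
# the response-list operator
# ---------------------------------------------------------------------------

_R_SOURCES = {9: {"r_diag": "Sq5", "r_left": "Sq8", "r_top": "Sq6"},
              4: {"r_diag": "Sq1", "r_left": "Sq3", "r_top": "Sq2"}}


def response_list(m: Matrix, seed: int = 0) -> ResponseList:
    """Generate the 11-option response list for a matrix.

    Degenerate options (equal to the correct response) and infeasible IC
    options are replaced by the crossed-out correct response; every such
    replacement is recorded as a warning.  Changing ``seed`` perturbs only
    the seed-dependent options (Difference and, in logic matrices, the
    random removal of ic_inc).
    """
    correct = correct_response(m)
    warnings: list[tuple[str, str]] = []
    options: dict[str, Figure | None] = {"correct": correct}

    for name, src in _R_SOURCES[m.mat_type].items():
        options[name] = m.cells[src]

    wp_copy, wp_matrix = gen_wrong_principle(m)
    options["wp_copy"] = wp_copy
    options["wp_matrix"] = wp_matrix

    diff, diff_warning = gen_difference(m, seed=seed)
    options["difference"] = diff
    if diff_warning:
        warnings.append(("difference", diff_warning))

    ic, ic_warnings = gen_incomplete_correlates(m, seed=seed)
    options.update(ic)
    warnings.extend(ic_warnings)

    # uniform fallback: infeasible or degenerate options become the
    # crossed-out correct response
    final: dict[str, Figure] = {}
    for name in OPTION_NAMES:
        fig = options[name]
        if name == "correct":
            final[name] = correct
            continue
        if fig is None:
            final[name] = crossed_out(correct)
            continue
        if figures_equal(fig, correct):
            warnings.append((name, f"{name} is equal to the correct response"))
            final[name] = crossed_out(correct)
            continue
        final[name] = fig

    return ResponseList(options=final, warnings=tuple(warnings), seed=seed)


def response_list_to_dict(rl: ResponseList) -> dict:
    """Serialize a response list; the key option is stored under 'correct'."""
    return {
        "options": {name: figure_to_dict(fig) for name, fig in rl.options.items()},
        "warnings": [list(w) for w in rl.warnings],
        "seed": rl.seed,
        "correct": "correct",
    }
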