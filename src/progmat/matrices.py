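"""Matrix construction (``mat_apply``), layering (``com``) and direction
classification.

A matrix is a named structure of cells ``Sq1..Sq4`` (2x2) or ``Sq1..Sq9``
(3x3), row-major with ``Sq1`` top-left, plus the horizontal and vertical rule
lists and the matrix type.  The blank, respondent-facing cell is always the
last one (``Sq4`` / ``Sq9``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    ArityError,
    MatrixDimensionError,
    RuleCombinationError,
    RuleConflictError,
    ValidationError,
)
from .figures import Figure, cof, figure_from_dict, figure_to_dict, make_primitive
from .rules import Rule, apply_rule, make_logical_row, resolve_rules

__all__ = [
    "Matrix",
    "build_matrix",
    "classify_direction",
    "com",
    "correct_response",
    "figure_spec_from_dict",
    "mat_apply",
    "matrix_to_dict",
    "n_rules",
]

DEFAULT_SEED = 1


@dataclass(frozen=True)
class Matrix:
    """A generated matrix: cells, directional rule lists and provenance.

    ``layer_rules`` keeps, per layer, the (hrules, vrules) used to build it;
    ``layer_sizes`` the per-cell element count each layer contributes.  Both
    are needed by the distractor generator.
    """

    cells: Mapping[str, Figure]
    hrule: tuple[str, ...]
    vrule: tuple[str, ...]
    mat_type: int
    seed: int = DEFAULT_SEED
    n_layers: int = 1
    layer_rules: tuple = ()
    layer_sizes: tuple = ()

    def __post_init__(self) -> None:
        if self.mat_type not in (4, 9):
            raise MatrixDimensionError(f"mat.type must be 4 or 9, got {self.mat_type}")
        expected = [f"Sq{i}" for i in range(1, self.mat_type + 1)]
        if list(self.cells) != expected:
            raise ValidationError(f"cells must be exactly {expected}, got {list(self.cells)}")

    @property
    def side(self) -> int:
        return 3 if self.mat_type == 9 else 2

    def names(self) -> list[str]:
        """The exposed structure names, in printed order."""
        return [f"Sq{i}" for i in range(1, self.mat_type + 1)] + ["hrule", "vrule", "mat.type"]

    def cell(self, row: int, col: int) -> Figure:
        """Cell at 1-based (row, col)."""
        return self.cells[f"Sq{(row - 1) * self.side + col}"]


def _as_name_list(rules: Sequence[str] | str) -> list[str]:
    return [rules] if isinstance(rules, str) else list(rules)


def _validate_logical(hr: list[Rule], vr: list[Rule], mat_type: int) -> Rule | None:
    """Enforce the logical-rule constraints; return the logical rule, if any."""
    h_logical = [r for r in hr if r.is_logical]
    v_logical = [r for r in vr if r.is_logical]
    logical = h_logical + v_logical
    if not logical:
        return None
    others = [r for r in hr + vr if not r.is_logical and not r.is_identity]
    if others:
        raise RuleCombinationError(
            f"logical rule {logical[0].name!r} cannot be combined with the "
            f"visuospatial rule {others[0].name!r}")
    if mat_type == 4:
        raise MatrixDimensionError(
            "a logical rule cannot be used to generate a four-cell matrix")
    if len(logical) > 1:
        names = sorted({r.name for r in logical})
        if len(names) > 1:
            raise RuleConflictError(
                f"two different logical rules with differing directional logic: {names}")
        raise RuleConflictError(
            f"logical rule {names[0]!r} cannot be applied in both directions at once")
    return logical[0]


def mat_apply(start: Figure, hrules: Sequence[str] | str = ("identity",),
              vrules: Sequence[str] | str = ("identity",), mat_type: int = 9,
              seed: int = DEFAULT_SEED) -> Matrix:
    """Build a single-layer matrix from a start figure and directional rules.

    Every cell is first populated with ``start``.  If a logical rule is
    present (and valid) the whole matrix is generated in one pass from seeded
    row/column partitions.  Otherwise each horizontal rule is applied across
    columns (step = 1-based column index) and then each vertical rule across
    rows (step = row index); a rule listed in both directions is applied
    twice, so its transformations accumulate.
    """
    if mat_type not in (4, 9):
        raise MatrixDimensionError(f"mat.type must be 4 or 9, got {mat_type}")
    hnames, vnames = _as_name_list(hrules), _as_name_list(vrules)
    hr, vr = resolve_rules(hnames), resolve_rules(vnames)
    side = 3 if mat_type == 9 else 2

    logical = _validate_logical(hr, vr, mat_type)
    grid = [[start for _ in range(side)] for _ in range(side)]

    if logical is not None:
        if any(r.is_logical for r in hr):
            for r_i in range(side):
                grid[r_i] = list(make_logical_row(logical, start, r_i + 1, seed))
        else:
            for c_i in range(side):
                col = make_logical_row(logical, start, c_i + 1, seed)
                for r_i in range(side):
                    grid[r_i][c_i] = col[r_i]
    else:
        for r in hr:
            for r_i in range(side):
                for c_i in range(side):
                    grid[r_i][c_i] = apply_rule(r, grid[r_i][c_i], n=c_i + 1)
        for r in vr:
            for r_i in range(side):
                for c_i in range(side):
                    grid[r_i][c_i] = apply_rule(r, grid[r_i][c_i], n=r_i + 1)

    cells = {f"Sq{r_i * side + c_i + 1}": grid[r_i][c_i]
             for r_i in range(side) for c_i in range(side)}
    return Matrix(cells=cells, hrule=tuple(hnames), vrule=tuple(vnames),
                  mat_type=mat_type, seed=seed, n_layers=1,
                  layer_rules=((tuple(hnames), tuple(vnames)),),
                  layer_sizes=(len(start.elements),))


def com(*layers: Matrix) -> Matrix:
    """Concatenate matrices into a multi-layer matrix, background first.

    Each cell of the result is the concatenation of the corresponding layer
    cells in layer order, so the last layer is drawn in the foreground.
    """
    if not layers:
        raise ArityError("com() needs at least one matrix")
    mat_type = layers[0].mat_type
    if any(m.mat_type != mat_type for m in layers):
        raise MatrixDimensionError("all layers must share the same mat.type")
    cells = {name: cof(*(m.cells[name] for m in layers)) for name in layers[0].cells}
    return Matrix(
        cells=cells,
        hrule=tuple(n for m in layers for n in m.hrule),
        vrule=tuple(n for m in layers for n in m.vrule),
        mat_type=mat_type,
        seed=layers[0].seed,
        n_layers=sum(m.n_layers for m in layers),
        layer_rules=tuple(lr for m in layers for lr in m.layer_rules),
        layer_sizes=tuple(s for m in layers for s in m.layer_sizes),
    )


def correct_response(m: Matrix) -> Figure:
    """Content of the blank (last) cell: the correct response option."""
    return m.cells[f"Sq{m.mat_type}"]


def classify_direction(m: Matrix) -> dict[str, str]:
    """Per rule family: H, V, TL-LR (forward+reverse), LL-TR or mixed.

    The identity rule is ignored.  A family present only horizontally is H,
    only vertically V.  When present in both directions it realizes a
    diagonal logic: TL-LR if exactly one direction is the reverse form,
    LL-TR if both are forward or both reverse.
    """
    h: dict[str, set] = {}
    v: dict[str, set] = {}
    for names, store in ((m.hrule, h), (m.vrule, v)):
        for name in names:
            r = resolve_rules(name)[0]
            if r.is_identity:
                continue
            store.setdefault(r.base, set()).add(r.direction == "reverse")
    out: dict[str, str] = {}
    for base in sorted(set(h) | set(v)):
        if base in h and base not in v:
            out[base] = "H" if len(h[base]) == 1 else "mixed"
        elif base in v and base not in h:
            out[base] = "V" if len(v[base]) == 1 else "mixed"
        else:
            if len(h[base]) > 1 or len(v[base]) > 1:
                out[base] = "mixed"
            elif h[base] != v[base]:
                out[base] = "TL-LR"
            else:
                out[base] = "LL-TR"
    return out


def n_rules(m: Matrix) -> int:
    """Number of distinct non-identity rule families manipulated."""
    return len(classify_direction(m))


# ---------------------------------------------------------------------------
# JSON item-spec
# ---------------------------------------------------------------------------

def figure_spec_from_dict(spec) -> Figure:
    """Materialize a figure from an item-spec fragment.

    Accepted forms: ``{"primitive": name, "overrides": {...}}``,
    ``{"cof": [fragments...], "single": bool, "name": str}`` or a full
    serialized figure (``{"elements": [...], ...}``).
    """
    if isinstance(spec, str):
        return make_primitive(spec)
    if not isinstance(spec, Mapping):
        raise ValidationError(f"bad figure spec: {spec!r}")
    if "primitive" in spec:
        return make_primitive(spec["primitive"], **spec.get("overrides", {}))
    if "cof" in spec:
        parts = [figure_spec_from_dict(p) for p in spec["cof"]]
        return cof(*parts, single=spec.get("single", False), name=spec.get("name"))
    if "elements" in spec:
        return figure_from_dict(spec)
    raise ValidationError(f"bad figure spec: {spec!r}")


def build_matrix(spec: Mapping) -> Matrix:
    """Build a (possibly multi-layer) matrix from a JSON item-spec.

    Keys: ``start`` (figure spec, or list of one per layer), ``hrules`` and
    ``vrules`` (rule-name list per layer, or a flat list for one layer),
    ``mat_type`` (4 or 9, default 9), ``seed``.
    """
    starts = spec.get("start")
    if starts is None:
        raise ValidationError("item spec needs a 'start' figure")
    if not isinstance(starts, list):
        starts = [starts]

    def per_layer(key):
        val = spec.get(key, [["identity"]] * len(starts))
        if val and not isinstance(val[0], list):
            val = [val]
        if len(val) != len(starts):
            raise ValidationError(
                f"{key} must give one rule list per layer ({len(starts)}), got {len(val)}")
        return val

    hrules, vrules = per_layer("hrules"), per_layer("vrules")
    mat_type = spec.get("mat_type", 9)
    seed = spec.get("seed", DEFAULT_SEED)
    layers = [
        mat_apply(figure_spec_from_dict(s), h, v, mat_type=mat_type, seed=seed)
        for s, h, v in zip(starts, hrules, vrules)
    ]
    return com(*layers)


def matrix_to_dict(m: Matrix) -> dict:
    """Serialize a matrix with all cells, rules and layer provenance."""
    return {
        "cells": {name: figure_to_dict(fig) for name, fig in m.cells.items()},
        "hrule": list(m.hrule),
        "vrule": list(m.vrule),
        "mat_type": m.mat_type,
        "seed": m.seed,
        "n_layers": m.n_layers,
        "layer_rules": [[list(h), list(v)] for h, v in m.layer_rules],
        "layer_sizes": list(m.layer_sizes),
    }
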