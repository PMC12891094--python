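"""Transformation rules: identity, margin (lwd/lty), rotation, size, shape,
shade, multi.shade and the logical AND/OR/XOR rules.

A rule is applied with a step index ``n`` that, inside a matrix, is linked to
the 1-based column index (horizontal direction) or row index (vertical
direction).  Incremental rules (rotation, size) are the identity at ``n = 1``
so the first cell of a row/column keeps the start figure; permutational rules
(lty, lwd, shade, shape) map ``n`` directly onto their value tables.
Logical rules have no cell-wise form: they generate a whole row or column at
once from a seeded partition of the figure's elements into three sets A, B
and C (see :func:`make_logical_row`).
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass
from typing import Iterable

from .errors import (
    ArityError,
    FeasibilityError,
    RegistryError,
    RuleRangeError,
    UnsupportedRuleError,
)
from .figures import (
    SHADES,
    Figure,
    rotate_figure,
    scale_figure,
    set_visibility,
    transform_elements,
)

__all__ = [
    "LOGICAL_RULES",
    "Rule",
    "apply_rule",
    "logical_partition",
    "make_logical_row",
    "rule",
    "rule_registry_lookup",
]

LOGICAL_RULES = ("AND", "OR", "XOR")

#: line-type codes: 1 = solid, 2 = dashed, 3 = dotted
_LTY_FORWARD = (2, 3, 1)   # n = 1..3 -> dashed, dotted, solid
_LTY_REVERSE = (2, 1, 3)   # n = 1..3 -> dashed, solid, dotted

_DEFAULT_K_FORWARD = 0.9
_DEFAULT_K_REVERSE = 0.6
_DEFAULT_THETA = math.pi / 4


@dataclass(frozen=True)
class Rule:
    """A named transformation with its category, direction and parameters."""

    name: str
    base: str                       # rule family without the ".inv" suffix
    category: str                   # identity | incremental | permutational | logical
    direction: str = "forward"      # forward | reverse
    theta: float | None = None      # rotation step (radians)
    k: float | None = None          # size constant
    lty_map: tuple | None = None
    shade_map: tuple | None = None

    @property
    def is_logical(self) -> bool:
        return self.category == "logical"

    @property
    def is_identity(self) -> bool:
        return self.category == "identity"


_ROTATION_RE = re.compile(r"^rotation\.([1-9])(\.inv)?$")

_UNSUPPORTED = {
    "shade.inv": "no reverse shade rule is available",
    "multi.shade.inv": "no reverse multi.shade rule is available",
    "AND.inv": "logical rules cannot be applied in reverse",
    "OR.inv": "logical rules cannot be applied in reverse",
    "XOR.inv": "logical rules cannot be applied in reverse",
}


def rule_registry_lookup(name: str) -> Rule:
    """Resolve a rule identifier (including ``.inv`` forms) to a :class:`Rule`."""
    if name in _UNSUPPORTED:
        raise UnsupportedRuleError(f"{name}: {_UNSUPPORTED[name]}")
    if name == "identity":
        return Rule("identity", "identity", "identity")
    if name == "size":
        return Rule("size", "size", "incremental", "forward", k=_DEFAULT_K_FORWARD)
    if name == "size.inv":
        return Rule("size.inv", "size", "incremental", "reverse", k=_DEFAULT_K_REVERSE)
    if name == "rotation":
        return Rule("rotation", "rotation", "incremental", "forward", theta=_DEFAULT_THETA)
    if name == "rotation.inv":
        return Rule("rotation.inv", "rotation", "incremental", "reverse", theta=_DEFAULT_THETA)
    m = _ROTATION_RE.match(name)
    if m:
        theta = math.pi / int(m.group(1))
        direction = "reverse" if m.group(2) else "forward"
        return Rule(name, "rotation", "incremental", direction, theta=theta)
    if name == "lwd":
        return Rule("lwd", "lwd", "permutational", "forward")
    if name == "lwd.inv":
        return Rule("lwd.inv", "lwd", "permutational", "reverse")
    if name == "lty":
        return Rule("lty", "lty", "permutational", "forward", lty_map=_LTY_FORWARD)
    if name == "lty.inv":
        return Rule("lty.inv", "lty", "permutational", "reverse", lty_map=_LTY_REVERSE)
    if name == "shape":
        return Rule("shape", "shape", "permutational", "forward")
    if name == "shape.inv":
        return Rule("shape.inv", "shape", "permutational", "reverse")
    if name == "shade":
        return Rule("shade", "shade", "permutational", "forward", shade_map=SHADES)
    if name == "multi.shade":
        return Rule("multi.shade", "multi.shade", "permutational", "forward", shade_map=SHADES)
    if name in LOGICAL_RULES:
        return Rule(name, name, "logical")
    raise RegistryError(f"unknown rule {name!r}")


#: short alias used throughout the package
rule = rule_registry_lookup


def _require_tag(r: Rule, fig: Figure, tag: str) -> None:
    if tag not in fig.tags:
        raise FeasibilityError(
            f"rule {r.name!r} requires the {tag!r} tag, absent from figure {fig.name!r}")


def _check_step(r: Rule, n: int, upper: int | None = None) -> None:
    if not isinstance(n, int) or n < 1:
        raise RuleRangeError(f"step index n must be an integer >= 1, got {n!r}")
    if upper is not None and n > upper:
        raise RuleRangeError(f"rule {r.name!r} admits n in [1, {upper}], got {n}")


def apply_rule(r: Rule | str, fig: Figure, n: int) -> Figure:
    """Apply a non-logical rule to a figure at step ``n``.

    Logical rules are rejected here: they define whole rows/columns, not
    single cells (use :func:`make_logical_row`).
    """
    if isinstance(r, str):
        r = rule_registry_lookup(r)
    if r.is_logical:
        raise FeasibilityError(
            f"logical rule {r.name!r} generates whole rows/columns; use make_logical_row()")

    if r.is_identity:
        _check_step(r, n)
        return fig

    if r.base == "size":
        _check_step(r, n)
        if n == 1:
            return fig
        factor = n * r.k
        return scale_figure(fig, factor if r.direction == "reverse" else 1.0 / factor)

    if r.base == "rotation":
        _check_step(r, n)
        _require_tag(r, fig, "rotate")
        angle = (n - 1) * r.theta
        if r.direction == "reverse":
            angle = -angle
        if angle == 0.0:
            return fig
        return rotate_figure(fig, angle)

    if r.base == "lwd":
        _check_step(r, n, upper=3)
        width = n if r.direction == "forward" else 4 - n
        return transform_elements(fig, lambda e: e.replace(lwd=width))

    if r.base == "lty":
        _check_step(r, n, upper=3)
        code = r.lty_map[n - 1]
        return transform_elements(fig, lambda e: e.replace(lty=code))

    if r.base == "shade":
        _check_step(r, n, upper=3)
        _require_tag(r, fig, "fill")
        fill = r.shade_map[n - 1]
        # previous fill is ignored; only fill-capable elements are recolored
        return transform_elements(
            fig, lambda e: e.replace(shade=fill) if "fill" in e.tag else e)

    if r.base == "multi.shade":
        _check_step(r, n, upper=3)
        _require_tag(r, fig, "fill")
        rng = random.Random(n)
        new = list(fig.elements)
        for grp in fig.groups:
            fill = rng.choice(r.shade_map)
            for i in grp:
                if "fill" in new[i].tag:
                    new[i] = new[i].replace(shade=fill)
        return fig.with_elements(new)

    if r.base == "shape":
        _check_step(r, n, upper=3)
        if fig.n_constituents != 3:
            raise ArityError(
                f"shape rule needs a concatenation of exactly 3 figures, got {fig.n_constituents}")
        order = (0, 1, 2) if r.direction == "forward" else (2, 1, 0)
        chosen = order[n - 1]
        out = set_visibility(fig, range(len(fig.elements)), 0)
        return set_visibility(out, fig.groups[chosen], 1)

    raise RegistryError(f"rule {r.name!r} has no application routine")  # pragma: no cover


# ---------------------------------------------------------------------------
# logical rules
# ---------------------------------------------------------------------------

def logical_partition(n_elements: int, index: int, seed: int) -> tuple[frozenset, frozenset, frozenset]:
    """Seeded partition of ``range(n_elements)`` into three non-empty sets.

    Element indices are shuffled with a generator seeded from ``seed`` and the
    row/column ``index``, then split into three contiguous blocks with sizes
    as equal as possible (remainder going to A, then B).
    """
    if n_elements < 3:
        raise ArityError(f"a logical partition needs >= 3 elements, got {n_elements}")
    rng = random.Random(f"partition:{seed}:{index}")
    idx = list(range(n_elements))
    rng.shuffle(idx)
    q, rem = divmod(n_elements, 3)
    sizes = [q + (1 if i < rem else 0) for i in range(3)]
    a = frozenset(idx[: sizes[0]])
    b = frozenset(idx[sizes[0]: sizes[0] + sizes[1]])
    c = frozenset(idx[sizes[0] + sizes[1]:])
    return a, b, c


def make_logical_row(r: Rule | str, fig: Figure, index: int, seed: int) -> tuple[Figure, Figure, Figure]:
    """Realize one row (or column) of a logical-rule matrix.

    The figure's elements are partitioned into sets A, B, C; the three cells
    show {A, C}, {A, B} and then the rule-specific third pattern:
    AND -> {A}, OR -> {A, B, C}, XOR -> {B, C}.  Cells are produced by
    visibility toggles, so hidden elements remain in every cell.
    """
    if isinstance(r, str):
        r = rule_registry_lookup(r)
    if not r.is_logical:
        raise FeasibilityError(f"{r.name!r} is not a logical rule")
    if len(fig.elements) < 3:
        raise ArityError(
            f"logical rule {r.name!r} needs a concatenation of at least 3 figures, "
            f"got {len(fig.elements)} element(s)")
    a, b, c = logical_partition(len(fig.elements), index, seed)
    third = {"AND": a, "OR": a | b | c, "XOR": b | c}[r.name]
    cells = []
    for shown in (a | c, a | b, third):
        cell = set_visibility(fig, range(len(fig.elements)), 0)
        cells.append(set_visibility(cell, shown, 1))
    return tuple(cells)


def resolve_rules(names: Iterable[str] | str) -> list[Rule]:
    """Resolve a rule-name list (or a single name) into Rule records."""
    if isinstance(names, str):
        names = [names]
    return [rule_registry_lookup(n) if isinstance(n, str) else n for n in names]
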