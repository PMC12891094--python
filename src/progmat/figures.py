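"""Figure data model, primitive registry and concatenation.

A drawable *figure* is an ordered sequence of *elements*, each described by a
fixed 15-field feature record (shape, ellipse axes, arc angles, rotation,
position, line style, draw mode, vertex count, fill, visibility and a tag
set).  Elements are grouped into named *constituents*: a primitive such as
``circle`` contributes one constituent with one element, while a composite
primitive such as ``square4`` (a square built from four line segments)
contributes one constituent with four elements.  Rules that count figures
count constituents; rules that partition content operate on elements.

Elements are drawn back-to-front in sequence order (painter's algorithm).
The drawing canvas of a single cell is the abstract square [-20, 20]^2.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ArityError, RegistryError, ValidationError

__all__ = [
    "CANVAS",
    "FIELD_NAMES",
    "NV_MIN",
    "NV_MAX",
    "SHADES",
    "Element",
    "Figure",
    "cof",
    "count_constituents",
    "figure_from_dict",
    "figure_to_dict",
    "figures_equal",
    "invert_fill",
    "list_primitives",
    "make_primitive",
    "mirror_figure",
    "primitive_tags",
    "register_primitive",
    "rotate_figure",
    "scale_figure",
    "set_visibility",
    "transform_elements",
    "visible_indices",
]

#: Cell canvas extent (each cell spans CANVAS x CANVAS).
CANVAS = (-20.0, 20.0)

#: Admissible vertex counts: 2 (lines) up to 100 (circle and ellipse).
NV_MIN, NV_MAX = 2, 100

#: Fill names admitted by the shade-based rules, in rule order.
SHADES = ("white", "gray", "black")

#: Canonical names of the 15 feature fields, serialization order.
FIELD_NAMES = (
    "shape",
    "size.x",
    "size.y",
    "theta.1",
    "theta.2",
    "rotation",
    "pos.x",
    "pos.y",
    "lty",
    "lwd",
    "num",
    "nv",
    "shade",
    "visible",
    "tag",
)

# python attribute spelling of each field, parallel to FIELD_NAMES
_ATTRS = (
    "shape",
    "size_x",
    "size_y",
    "theta_1",
    "theta_2",
    "rotation",
    "pos_x",
    "pos_y",
    "lty",
    "lwd",
    "num",
    "nv",
    "shade",
    "visible",
    "tag",
)

_FIELD_TO_ATTR = dict(zip(FIELD_NAMES, _ATTRS))
_NUMERIC_ATTRS = ("size_x", "size_y", "theta_1", "theta_2", "rotation", "pos_x", "pos_y")


@dataclass(frozen=True)
class Element:
    """One 15-field feature record.

    ``num`` selects the draw mode: 1 = polygon with ``nv`` vertices inscribed
    in the (``size_x``, ``size_y``) ellipse, 2 = circular arc from ``theta_1``
    to ``theta_2``.  ``rotation`` is clockwise-positive.  ``visible`` is an
    integer level: 0 hides the element, any level >= 1 draws it.
    """

    shape: str
    size_x: float = 15.0
    size_y: float = 15.0
    theta_1: float = 0.0
    theta_2: float = 2.0 * math.pi
    rotation: float = 0.0
    pos_x: float = 0.0
    pos_y: float = 0.0
    lty: int = 1
    lwd: int = 1
    num: int = 1
    nv: int = 4
    shade: str | None = None
    visible: int = 1
    tag: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.shape:
            raise ValidationError("element shape name must be non-empty")
        if not (self.size_x > 0 and self.size_y > 0):
            raise ValidationError(f"size.x and size.y must be > 0, got ({self.size_x}, {self.size_y})")
        if self.num not in (1, 2):
            raise ValidationError(f"num must be 1 (polygon) or 2 (arc), got {self.num}")
        if not (NV_MIN <= self.nv <= NV_MAX):
            raise ValidationError(f"nv must be in [{NV_MIN}, {NV_MAX}], got {self.nv}")
        if self.visible < 0:
            raise ValidationError(f"visible must be >= 0, got {self.visible}")
        if self.lwd not in (1, 2, 3):
            raise ValidationError(f"lwd must be 1, 2 or 3, got {self.lwd}")
        if self.lty not in (1, 2, 3):
            raise ValidationError(f"lty must be 1 (solid), 2 (dashed) or 3 (dotted), got {self.lty}")
        if self.shade is not None and self.shade not in SHADES:
            raise ValidationError(f"shade must be one of {SHADES} or None, got {self.shade!r}")
        if not isinstance(self.tag, frozenset):
            object.__setattr__(self, "tag", frozenset(self.tag))

    def replace(self, **changes) -> "Element":
        """Return a copy with the given fields changed (dotted names accepted)."""
        changes = {_FIELD_TO_ATTR.get(k, k).replace(".", "_"): v for k, v in changes.items()}
        unknown = set(changes) - set(_ATTRS)
        if unknown:
            raise ValidationError(f"unknown feature field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {}
        for name, attr in zip(FIELD_NAMES, _ATTRS):
            v = getattr(self, attr)
            d[name] = sorted(v) if attr == "tag" else v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Element":
        kw = {}
        for name, attr in zip(FIELD_NAMES, _ATTRS):
            if name in d:
                v = d[name]
                kw[attr] = frozenset(v) if attr == "tag" else v
        return cls(**kw)


@dataclass(frozen=True)
class Figure:
    """An ordered collection of elements grouped into named constituents.

    ``names`` holds one name per constituent; ``groups`` holds, parallel to
    ``names``, the tuple of element indices belonging to each constituent.
    A figure forced to be *single* has exactly one name regardless of how
    many elements it contains.
    """

    elements: tuple[Element, ...]
    names: tuple[str, ...]
    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not isinstance(self.elements, tuple):
            object.__setattr__(self, "elements", tuple(self.elements))
        if not isinstance(self.names, tuple):
            object.__setattr__(self, "names", tuple(self.names))
        if not isinstance(self.groups, tuple):
            object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))
        if len(self.elements) < 1:
            raise ValidationError("a figure needs at least one element")
        if len(self.names) != len(self.groups) or len(self.names) < 1:
            raise ValidationError("names and groups must be parallel and non-empty")
        covered = [i for g in self.groups for i in g]
        if sorted(covered) != list(range(len(self.elements))):
            raise ValidationError("groups must partition the element sequence")

    # -- convenience views -------------------------------------------------
    @property
    def name(self) -> str:
        return self.names[0] if len(self.names) == 1 else "+".join(self.names)

    @property
    def tags(self) -> frozenset:
        out: frozenset = frozenset()
        for e in self.elements:
            out |= e.tag
        return out

    @property
    def n_constituents(self) -> int:
        return len(self.names)

    def constituent_tags(self, i: int) -> frozenset:
        out: frozenset = frozenset()
        for j in self.groups[i]:
            out |= self.elements[j].tag
        return out

    def with_elements(self, elements: Sequence[Element]) -> "Figure":
        if len(elements) != len(self.elements):
            raise ValidationError("element count cannot change")
        return Figure(tuple(elements), self.names, self.groups)


def visible_indices(fig: Figure) -> frozenset:
    """Indices of elements drawn (visibility level >= 1)."""
    return frozenset(i for i, e in enumerate(fig.elements) if e.visible >= 1)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def cof(*figs: Figure, single: bool = False, name: str | None = None) -> Figure:
    """Concatenate figures; later arguments are drawn on top.

    With ``single=True`` the result is forced to be one figure with the
    supplied ``name`` (rules that count figures then see one constituent).
    """
    if not figs:
        raise ArityError("cof() needs at least one figure")
    if single and not name:
        raise ValidationError("cof(single=True) requires a name for the merged figure")
    elements: list[Element] = []
    names: list[str] = []
    groups: list[tuple[int, ...]] = []
    for fig in figs:
        offset = len(elements)
        elements.extend(fig.elements)
        for gname, grp in zip(fig.names, fig.groups):
            names.append(gname)
            groups.append(tuple(offset + i for i in grp))
    if single:
        return Figure(tuple(elements), (name,), (tuple(range(len(elements))),))
    return Figure(tuple(elements), tuple(names), tuple(groups))


def count_constituents(fig: Figure) -> int:
    """Number of figures seen by arity-sensitive rules (single-forced = 1)."""
    return fig.n_constituents


def set_visibility(fig: Figure, indices: Iterable[int], level: int) -> Figure:
    """Copy of ``fig`` with ``visible`` set to ``level`` on the given elements.

    Hidden elements stay in the structure so logical rules can toggle them
    back on.
    """
    idx = set(indices)
    bad = [i for i in idx if not (0 <= i < len(fig.elements))]
    if bad:
        raise ValidationError(f"element index out of range: {bad}")
    new = [e.replace(visible=level) if i in idx else e for i, e in enumerate(fig.elements)]
    return fig.with_elements(new)


# ---------------------------------------------------------------------------
# geometric element transforms (shared by rules and distractor generation)
# ---------------------------------------------------------------------------

def transform_elements(fig: Figure, fn: Callable[[Element], Element],
                       indices: Iterable[int] | None = None) -> Figure:
    """Apply ``fn`` to the selected elements (all by default)."""
    idx = set(range(len(fig.elements))) if indices is None else set(indices)
    new = [fn(e) if i in idx else e for i, e in enumerate(fig.elements)]
    return fig.with_elements(new)


def rotate_figure(fig: Figure, angle_cw: float, indices: Iterable[int] | None = None) -> Figure:
    """Rotate elements clockwise by ``angle_cw`` about the canvas center."""
    c, s = math.cos(angle_cw), math.sin(angle_cw)

    def rot(e: Element) -> Element:
        x, y = e.pos_x, e.pos_y
        return e.replace(rotation=e.rotation + angle_cw,
                         pos_x=x * c + y * s, pos_y=-x * s + y * c)

    return transform_elements(fig, rot, indices)


def scale_figure(fig: Figure, factor: float, indices: Iterable[int] | None = None) -> Figure:
    """Scale element sizes and positions about the canvas center."""
    if factor <= 0:
        raise ValidationError(f"scale factor must be > 0, got {factor}")

    def sc(e: Element) -> Element:
        return e.replace(size_x=e.size_x * factor, size_y=e.size_y * factor,
                         pos_x=e.pos_x * factor, pos_y=e.pos_y * factor)

    return transform_elements(fig, sc, indices)


def mirror_figure(fig: Figure, indices: Iterable[int] | None = None) -> Figure:
    """Mirror elements across the vertical canvas axis (left-right flip)."""

    def mir(e: Element) -> Element:
        return e.replace(pos_x=-e.pos_x, rotation=-e.rotation,
                         theta_1=math.pi - e.theta_2, theta_2=math.pi - e.theta_1)

    return transform_elements(fig, mir, indices)


#: fill inversion used by the IC-Neg distractor
_FILL_INVERSION = {"white": "black", "black": "white", "gray": "black", None: "black"}


def invert_fill(fig: Figure, indices: Iterable[int] | None = None) -> Figure:
    """Invert the fill of fill-capable elements (white <-> black, else black)."""

    def inv(e: Element) -> Element:
        if "fill" not in e.tag:
            return e
        return e.replace(shade=_FILL_INVERSION[e.shade])

    return transform_elements(fig, inv, indices)


# ---------------------------------------------------------------------------
# equality & serialization
# ---------------------------------------------------------------------------

def figures_equal(a: Figure, b: Figure, tol: float = 1e-9) -> bool:
    """Field-wise comparison of the *visible* elements of two figures.

    Discrete fields must match exactly; numeric fields within ``tol``.
    Element order matters (it is the draw order).
    """
    va = [a.elements[i] for i in sorted(visible_indices(a))]
    vb = [b.elements[i] for i in sorted(visible_indices(b))]
    if len(va) != len(vb):
        return False
    for ea, eb in zip(va, vb):
        for attr in _ATTRS:
            x, y = getattr(ea, attr), getattr(eb, attr)
            if attr in _NUMERIC_ATTRS:
                if abs(x - y) > tol:
                    return False
            elif x != y:
                return False
    return True


def figure_to_dict(fig: Figure) -> dict:
    """Serialize to the JSON item-spec dialect (all 15 fields per element)."""
    return {
        "name": fig.name,
        "elements": [e.to_dict() for e in fig.elements],
        "tags": sorted(fig.tags),
        "constituents": [
            {"name": n, "elements": list(g)} for n, g in zip(fig.names, fig.groups)
        ],
    }


def figure_from_dict(d: Mapping) -> Figure:
    elements = tuple(Element.from_dict(e) for e in d["elements"])
    if "constituents" in d:
        names = tuple(c["name"] for c in d["constituents"])
        groups = tuple(tuple(c["elements"]) for c in d["constituents"])
    else:
        names = (d.get("name", elements[0].shape),)
        groups = (tuple(range(len(elements))),)
    return Figure(elements, names, groups)


# ---------------------------------------------------------------------------
# primitive registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PrimitiveSpec:
    builder: Callable[[], tuple[Element, ...]]
    tags: frozenset


_REGISTRY: dict[str, _PrimitiveSpec] = {}


def register_primitive(name: str, builder: Callable[[], Sequence[Element]],
                       tags: Iterable[str]) -> None:
    """Register a user-defined primitive.

    ``builder`` returns the element sequence; ``tags`` gate which rules and
    distractor manipulations apply (``fill`` for shading, ``rotate`` for
    rotation, ``d.ext``/``d.int`` for use as Difference-distractor material).
    """
    tags = frozenset(tags)
    if not tags:
        raise ValidationError(f"primitive {name!r} must carry at least one tag")
    _REGISTRY[name] = _PrimitiveSpec(lambda: tuple(builder()), tags)


def list_primitives(tagged: str | None = None) -> list[str]:
    """Registered primitive names, optionally restricted to one tag."""
    if tagged is None:
        return sorted(_REGISTRY)
    return sorted(n for n, s in _REGISTRY.items() if tagged in s.tags)


def primitive_tags(name: str) -> frozenset:
    if name not in _REGISTRY:
        raise RegistryError(f"unknown primitive {name!r}")
    return _REGISTRY[name].tags


def make_primitive(name: str, **overrides) -> Figure:
    """Instantiate a registered primitive, applying feature overrides.

    Overrides use the feature field names (``size_x=10`` or ``**{"size.x": 10}``)
    and are applied to every element of the primitive.
    """
    if name not in _REGISTRY:
        raise RegistryError(f"unknown primitive {name!r}; known: {list_primitives()}")
    spec = _REGISTRY[name]
    elements = []
    for e in spec.builder():
        if not e.tag >= spec.tags:  # registry tags are stamped on every element
            e = e.replace(tag=e.tag | spec.tags)
        if overrides:
            e = e.replace(**overrides)
        elements.append(e)
    return Figure(tuple(elements), (name,), (tuple(range(len(elements))),))


# -- builders ----------------------------------------------------------------

def _el(shape, tags, **kw) -> Element:
    return Element(shape=shape, tag=frozenset(tags), **kw)


def _register_defaults() -> None:
    # closed figures -------------------------------------------------------
    simple_closed = ("simple", "fill", "d.ext", "rotate")
    _REGISTRY["square"] = _PrimitiveSpec(
        lambda: (_el("square", simple_closed, nv=4, rotation=math.pi / 4),), frozenset(simple_closed))
    _REGISTRY["triangle"] = _PrimitiveSpec(
        lambda: (_el("triangle", simple_closed, nv=3),), frozenset(simple_closed))
    _REGISTRY["pentagon"] = _PrimitiveSpec(
        lambda: (_el("pentagon", simple_closed, nv=5),), frozenset(simple_closed))
    _REGISTRY["hexagon"] = _PrimitiveSpec(
        lambda: (_el("hexagon", simple_closed, nv=6),), frozenset(simple_closed))

    circle_tags = ("simple", "fill", "d.ext")  # rotation of a circle is invisible
    _REGISTRY["circle"] = _PrimitiveSpec(
        lambda: (_el("circle", circle_tags, nv=NV_MAX),), frozenset(circle_tags))
    ellipse_tags = ("simple", "fill", "d.ext", "rotate")
    _REGISTRY["ellipse"] = _PrimitiveSpec(
        lambda: (_el("ellipse", ellipse_tags, nv=NV_MAX, size_y=9.0),), frozenset(ellipse_tags))

    # black figures --------------------------------------------------------
    dot_tags = ("simple", "d.int")
    _REGISTRY["dot"] = _PrimitiveSpec(
        lambda: (_el("dot", dot_tags, nv=NV_MAX, size_x=2.5, size_y=2.5, shade="black"),),
        frozenset(dot_tags))

    # circle sections --------------------------------------------------------
    semi_tags = ("simple", "d.ext", "rotate")
    _REGISTRY["semicircle"] = _PrimitiveSpec(
        lambda: (_el("semicircle", semi_tags, num=2, nv=50, theta_1=0.0, theta_2=math.pi),),
        frozenset(semi_tags))

    # lines ------------------------------------------------------------------
    line_tags = ("simple", "d.ext", "rotate")
    _REGISTRY["vline"] = _PrimitiveSpec(
        lambda: (_el("vline", line_tags, nv=2),), frozenset(line_tags))
    _REGISTRY["hline"] = _PrimitiveSpec(
        lambda: (_el("hline", line_tags, nv=2, rotation=math.pi / 2),), frozenset(line_tags))

    # other: plus sign of two lines -----------------------------------------
    cross_tags = ("compose2", "d.int", "rotate")
    _REGISTRY["cross"] = _PrimitiveSpec(
        lambda: (_el("cross", cross_tags, nv=2),
                 _el("cross", cross_tags, nv=2, rotation=math.pi / 2)),
        frozenset(cross_tags))

    # square built from 4 line segments -------------------------------------
    sq4_tags = ("compose4", "d.int", "rotate")

    def _square4():
        side, half = 10.0, 10.0
        return (
            _el("square4", sq4_tags, nv=2, size_y=side, rotation=math.pi / 2, pos_x=0.0, pos_y=half),
            _el("square4", sq4_tags, nv=2, size_y=side, rotation=math.pi / 2, pos_x=0.0, pos_y=-half),
            _el("square4", sq4_tags, nv=2, size_y=side, pos_x=-half, pos_y=0.0),
            _el("square4", sq4_tags, nv=2, size_y=side, pos_x=half, pos_y=0.0),
        )

    _REGISTRY["square4"] = _PrimitiveSpec(_square4, frozenset(sq4_tags))

    # flower of 4 petals; cannot change fill, rotation maps it onto itself ---
    miley_tags = ("compose4", "d.int")

    def _miley():
        petals = []
        for k in range(4):
            ang = k * math.pi / 2
            px, py = 7.5 * math.sin(ang), 7.5 * math.cos(ang)
            petals.append(_el("miley", miley_tags, nv=NV_MAX, size_x=3.5, size_y=7.0,
                              rotation=ang, pos_x=px, pos_y=py))
        return tuple(petals)

    _REGISTRY["miley"] = _PrimitiveSpec(_miley, frozenset(miley_tags))

    # malta cross of 4 triangular blades; fillable but not rotatable ---------
    malta_tags = ("compose4", "fill", "d.int")

    def _malta():
        blades = []
        for k in range(4):
            ang = k * math.pi / 2
            px, py = 8.0 * math.sin(ang), 8.0 * math.cos(ang)
            # blade points outward: triangle rotated so its apex faces away
            blades.append(_el("malta", malta_tags, nv=3, size_x=6.0, size_y=6.0,
                              rotation=ang + math.pi, pos_x=px, pos_y=py))
        return tuple(blades)

    _REGISTRY["malta"] = _PrimitiveSpec(_malta, frozenset(malta_tags))

    # eight-shaped: two stacked circles --------------------------------------
    eight_tags = ("compose2", "fill", "d.int")

    def _eight():
        return (_el("eight", eight_tags, nv=NV_MAX, size_x=6.0, size_y=6.0, pos_y=7.0),
                _el("eight", eight_tags, nv=NV_MAX, size_x=6.0, size_y=6.0, pos_y=-7.0))

    _REGISTRY["eight"] = _PrimitiveSpec(_eight, frozenset(eight_tags))


_register_defaults()
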