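"""Rendering of figures, matrices and response lists to SVG/PNG.

Each cell is drawn on the fixed abstract canvas [-20, 20]^2.  Elements are
painted in sequence order (painter's algorithm); invisible elements are
skipped; the blank last cell of a matrix never contributes drawable content.
SVG output is deterministic for a fixed object and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as MplPolygon

from .errors import SelectionError, ValidationError
from .figures import CANVAS, Element, Figure
from .matrices import Matrix
from .responses import ResponseList

__all__ = ["RenderSpec", "draw", "element_path", "export", "export_split"]

# deterministic SVG ids
matplotlib.rcParams["svg.hashsalt"] = "progmat"

_SHADE_HEX = {"white": "#FFFFFF", "gray": "#808080", "black": "#000000"}
#: lty codes -> dash pattern (canvas units); 1 solid, 2 dashed, 3 dotted
_LTY_DASH = {1: "solid", 2: (0, (6, 4)), 3: (0, (1, 3))}
_MARGIN = 0.05  # fraction of canvas kept clear around each panel


@dataclass(frozen=True)
class RenderSpec:
    """Canvas, layout, label and export options."""

    show_labels: bool = False
    labels: tuple | None = None
    subset: tuple | None = None
    fmt: str = "svg"
    dpi: int = 100
    composite: bool = True
    question_mark: bool = False  # optional "?" glyph in the blank cell
    cell_size: float = 2.0       # panel edge in inches


def element_path(e: Element) -> tuple[np.ndarray, np.ndarray, bool]:
    """Vertex coordinates of an element and whether the path is closed.

    Polygons (``num=1``) are regular ``nv``-gons inscribed in the
    (size.x, size.y) ellipse, first vertex at the top; arcs (``num=2``)
    sample the ellipse between theta.1 and theta.2.  ``rotation`` is applied
    clockwise about (pos.x, pos.y).
    """
    if e.num == 2:
        t = np.linspace(e.theta_1, e.theta_2, max(e.nv, 8))
        closed = False
    else:
        t = math.pi / 2 + np.arange(e.nv) * 2.0 * math.pi / e.nv
        closed = e.nv > 2
    x0 = e.size_x * np.cos(t)
    y0 = e.size_y * np.sin(t)
    a = e.rotation  # clockwise positive
    x = e.pos_x + x0 * math.cos(a) + y0 * math.sin(a)
    y = e.pos_y - x0 * math.sin(a) + y0 * math.cos(a)
    return x, y, closed


def _paint_element(ax, e: Element) -> None:
    if e.visible < 1:
        return
    x, y, closed = element_path(e)
    lw = 1.2 * e.lwd
    ls = _LTY_DASH[e.lty]
    if closed and e.shade is not None:
        ax.add_patch(MplPolygon(np.column_stack([x, y]), closed=True,
                                facecolor=_SHADE_HEX[e.shade], edgecolor="black",
                                linewidth=lw, linestyle=ls, zorder=2))
    elif closed:
        ax.add_patch(MplPolygon(np.column_stack([x, y]), closed=True,
                                fill=False, edgecolor="black",
                                linewidth=lw, linestyle=ls, zorder=2))
    else:
        ax.plot(x, y, color="black", linewidth=lw, linestyle=ls, zorder=2)


def _panel(ax, fig: Figure | None, label: str | None = None,
           question_mark: bool = False) -> None:
    lo, hi = CANVAS
    pad = (hi - lo) * _MARGIN
    ax.set_xlim(lo - pad, hi + pad)
    ax.set_ylim(lo - pad, hi + pad)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    for side in ax.spines.values():
        side.set_linewidth(0.8)
    if fig is not None:
        for e in fig.elements:
            _paint_element(ax, e)
    elif question_mark:
        ax.text(0, 0, "?", ha="center", va="center", fontsize=24)
    if label:
        ax.set_title(label, fontsize=9)


def _grid_figure(n_panels: int, ncols: int, cell_size: float):
    nrows = math.ceil(n_panels / ncols)
    mpl_fig, axes = plt.subplots(nrows, ncols,
                                 figsize=(ncols * cell_size, nrows * cell_size))
    axes = np.atleast_1d(axes).ravel()
    for ax in axes[n_panels:]:
        mpl_fig.delaxes(ax)
    return mpl_fig, axes[:n_panels]


def draw(obj: Figure | Matrix | ResponseList, spec: RenderSpec | None = None, **kw):
    """Render an object to a matplotlib figure (one axes per panel).

    Figures give one panel; matrices a 2x2/3x3 grid with the last cell
    blank; response lists one panel per option, in canonical order or in the
    order of ``subset``.  Keyword arguments override :class:`RenderSpec`
    fields.
    """
    if spec is None:
        spec = RenderSpec()
    if kw:
        spec = RenderSpec(**{**spec.__dict__, **kw})

    if isinstance(obj, Figure):
        mpl_fig, axes = _grid_figure(1, 1, spec.cell_size)
        label = spec.labels[0] if spec.labels else None
        _panel(axes[0], obj, label)
        return mpl_fig

    if isinstance(obj, Matrix):
        side = obj.side
        mpl_fig, axes = _grid_figure(side * side, side, spec.cell_size)
        names = [f"Sq{i}" for i in range(1, obj.mat_type + 1)]
        if spec.labels is not None and len(spec.labels) != len(names):
            raise ValidationError(
                f"labels length {len(spec.labels)} != panel count {len(names)}")
        for i, (ax, name) in enumerate(zip(axes, names)):
            blank = name == f"Sq{obj.mat_type}"
            label = None
            if spec.labels is not None:
                label = spec.labels[i]
            elif spec.show_labels:
                label = name
            _panel(ax, None if blank else obj.cells[name], label,
                   question_mark=blank and spec.question_mark)
        mpl_fig.tight_layout()
        return mpl_fig

    if isinstance(obj, ResponseList):
        names = list(spec.subset) if spec.subset is not None else list(obj.options)
        unknown = [n for n in names if n not in obj.options]
        if unknown:
            raise SelectionError(f"unknown response option(s): {unknown}")
        if spec.labels is not None and len(spec.labels) != len(names):
            raise ValidationError(
                f"labels length {len(spec.labels)} != panel count {len(names)}")
        mpl_fig, axes = _grid_figure(len(names), min(4, len(names)), spec.cell_size)
        for i, (ax, name) in enumerate(zip(axes, names)):
            if spec.labels is not None:
                label = spec.labels[i]
            else:
                label = name if spec.show_labels else None
            _panel(ax, obj.options[name], label)
        mpl_fig.tight_layout()
        return mpl_fig

    raise ValidationError(f"cannot draw object of type {type(obj).__name__}")


def _save(mpl_fig, path: Path, fmt: str, dpi: int) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kw = {"format": fmt, "dpi": dpi}
    if fmt == "svg":
        kw["metadata"] = {"Date": None}  # byte-stable output
    mpl_fig.savefig(path, **kw)
    plt.close(mpl_fig)
    return path


def export(obj, path, fmt: str | None = None, spec: RenderSpec | None = None, **kw) -> Path:
    """Render ``obj`` and write one composite image (SVG or PNG)."""
    path = Path(path)
    if fmt is None:
        fmt = (path.suffix.lstrip(".") or "svg").lower()
    spec = spec or RenderSpec(fmt=fmt)
    if kw:
        spec = RenderSpec(**{**spec.__dict__, **kw})
    mpl_fig = draw(obj, spec)
    return _save(mpl_fig, path, fmt, spec.dpi)


def export_split(obj: Matrix | ResponseList, out_dir, stem: str,
                 fmt: str = "svg", dpi: int = 100,
                 cell_size: float = 2.0) -> list[Path]:
    """Write one file per cell (``<stem>_SqN``) or option (``<stem>_<name>``)."""
    out_dir = Path(out_dir)
    paths = []
    if isinstance(obj, Matrix):
        panels = [(f"Sq{i}",
                   None if i == obj.mat_type else obj.cells[f"Sq{i}"])
                  for i in range(1, obj.mat_type + 1)]
    elif isinstance(obj, ResponseList):
        panels = list(obj.options.items())
    else:
        raise ValidationError(f"cannot split-export object of type {type(obj).__name__}")
    for name, fig in panels:
        mpl_fig, axes = _grid_figure(1, 1, cell_size)
        _panel(axes[0], fig)
        paths.append(_save(mpl_fig, out_dir / f"{stem}_{name}.{fmt}", fmt, dpi))
    return paths
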