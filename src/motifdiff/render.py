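"""Drawing backends for logo geometry: SVG (native), PNG/PDF (matplotlib).

Letters are drawn from a built-in 5x7 polygon glyph set rather than from
fonts, so vector output is portable and byte-stable across systems (SVG
output for identical input is byte-identical; no timestamps are embedded).
Each rendered stack segment becomes exactly one ``<path>`` element of class
``glyph`` whose subpaths are the filled cells of the letter bitmap, holes
(letter counters) included.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .compare import ComparisonGrid
from .errors import MotifError
from .geometry import LogoColumns

# 5x7 bitmap outlines for A-Z; '#' cells are filled.
_FONT = {
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "B": ("####.", "#...#", "#...#", "####.", "#...#", "#...#", "####."),
    "C": (".###.", "#...#", "#....", "#....", "#....", "#...#", ".###."),
    "D": ("####.", "#...#", "#...#", "#...#", "#...#", "#...#", "####."),
    "E": ("#####", "#....", "#....", "####.", "#....", "#....", "#####"),
    "F": ("#####", "#....", "#....", "####.", "#....", "#....", "#...."),
    "G": (".###.", "#...#", "#....", "#.###", "#...#", "#...#", ".###."),
    "H": ("#...#", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "I": (".###.", "..#..", "..#..", "..#..", "..#..", "..#..", ".###."),
    "J": ("..###", "...#.", "...#.", "...#.", "...#.", "#..#.", ".##.."),
    "K": ("#...#", "#..#.", "#.#..", "##...", "#.#..", "#..#.", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#....", "#....", "#####"),
    "M": ("#...#", "##.##", "#.#.#", "#.#.#", "#...#", "#...#", "#...#"),
    "N": ("#...#", "##..#", "#.#.#", "#..##", "#...#", "#...#", "#...#"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "P": ("####.", "#...#", "#...#", "####.", "#....", "#....", "#...."),
    "Q": (".###.", "#...#", "#...#", "#...#", "#.#.#", "#..#.", ".##.#"),
    "R": ("####.", "#...#", "#...#", "####.", "#.#..", "#..#.", "#...#"),
    "S": (".####", "#....", "#....", ".###.", "....#", "....#", "####."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "V": ("#...#", "#...#", "#...#", "#...#", "#...#", ".#.#.", "..#.."),
    "W": ("#...#", "#...#", "#...#", "#.#.#", "#.#.#", "##.##", "#...#"),
    "X": ("#...#", "#...#", ".#.#.", "..#..", ".#.#.", "#...#", "#...#"),
    "Y": ("#...#", "#...#", ".#.#.", "..#..", "..#..", "..#..", "..#.."),
    "Z": ("#####", "....#", "...#.", "..#..", ".#...", "#....", "#####"),
}
_FALLBACK = ("#####", "#...#", "#...#", "#...#", "#...#", "#...#", "#####")

_GRID_ROWS, _GRID_COLS = 7, 5


def glyph_rects(symbol: str):
    """Unit-box rectangles (x, y, w, h), y downward, for one letter.

    Consecutive filled cells in a row merge into one rectangle; letter
    counters (the holes of A, B, O, ...) arise naturally as unfilled cells.
    """
    bitmap = _FONT.get(symbol.upper(), _FALLBACK)
    rects = []
    for r, row in enumerate(bitmap):
        c = 0
        while c < _GRID_COLS:
            if row[c] == "#":
                start = c
                while c < _GRID_COLS and row[c] == "#":
                    c += 1
                rects.append(
                    (start / _GRID_COLS, r / _GRID_ROWS, (c - start) / _GRID_COLS, 1 / _GRID_ROWS)
                )
            else:
                c += 1
    return rects


@dataclass(frozen=True)
class FigureSpec:
    """Figure layout parameters (pixels unless noted)."""

    column_width: float = 40.0      # width of one motif position in a logo
    logo_height: float = 160.0      # plot height of a standalone logo
    margin_left: float = 52.0
    margin_right: float = 12.0
    margin_top: float = 14.0
    margin_bottom: float = 42.0
    font_size: float = 12.0
    axis_label_x: str = "position"
    axis_label_y: str = "bits"
    # grid-specific bands
    cell_width: float = 120.0
    cell_height: float = 80.0
    cell_gap: float = 3.0
    label_band: float = 22.0
    tree_band: float = 56.0
    header_logo_band: float = 64.0
    dpi: int = 150

    def __post_init__(self):
        if min(self.column_width, self.logo_height, self.cell_width, self.cell_height) <= 0:
            raise MotifError("figure dimensions must be positive")


def _fmt(x: float) -> str:
    return format(float(x), ".3f")


class _Svg:
    """Minimal deterministic SVG document builder."""

    def __init__(self, width: float, height: float):
        self.width, self.height = width, height
        self.parts = []

    def rect(self, x, y, w, h, fill, cls=None, stroke=None):
        attrs = f'x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" height="{_fmt(h)}" fill="{fill}"'
        if stroke:
            attrs += f' stroke="{stroke}"'
        if cls:
            attrs += f' class="{cls}"'
        self.parts.append(f"<rect {attrs}/>")

    def line(self, x1, y1, x2, y2, stroke="#000000", width=1.0, cls=None):
        attrs = (
            f'x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="{stroke}" stroke-width="{_fmt(width)}"'
        )
        if cls:
            attrs += f' class="{cls}"'
        self.parts.append(f"<line {attrs}/>")

    def path(self, d, fill, cls=None, extra=""):
        attrs = f'd="{d}" fill="{fill}"'
        if cls:
            attrs += f' class="{cls}"'
        if extra:
            attrs += " " + extra
        self.parts.append(f"<path {attrs}/>")

    def text(self, x, y, content, size, anchor="middle", cls=None, rotate=None):
        esc = (
            str(content)
            .replace("&", "&amp;")
            .replace("<", "&lt;")
            .replace(">", "&gt;")
        )
        attrs = (
            f'x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(size)}" '
            f'text-anchor="{anchor}" font-family="sans-serif"'
        )
        if rotate is not None:
            attrs += f' transform="rotate({_fmt(rotate)} {_fmt(x)} {_fmt(y)})"'
        if cls:
            attrs += f' class="{cls}"'
        self.parts.append(f"<text {attrs}>{esc}</text>")

    def tostring(self) -> str:
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(self.width)}" '
            f'height="{_fmt(self.height)}" viewBox="0 0 {_fmt(self.width)} {_fmt(self.height)}">'
        )
        return head + "\n" + "\n".join(self.parts) + "\n</svg>\n"


def _glyph_path_d(symbol: str, x: float, y_top: float, w: float, h: float) -> str:
    """SVG path data for one letter scaled into the (x, y_top, w, h) box."""
    sub = []
    for rx, ry, rw, rh in glyph_rects(symbol):
        x0, y0 = x + rx * w, y_top + ry * h
        sub.append(
            f"M{_fmt(x0)} {_fmt(y0)}h{_fmt(rw * w)}v{_fmt(rh * h)}h{_fmt(-rw * w)}Z"
        )
    return "".join(sub)


# fraction of a position width left blank on each side of a letter
_X_PAD = 0.04


def _draw_columns(svg: _Svg, cols: LogoColumns, x0, y0, plot_w, plot_h, cls="glyph"):
    """Draw the letter stacks of one logo into the given plot box."""
    span = cols.ordinate_max - cols.ordinate_min
    if span <= 0:
        return

    def sx(pos):  # data x (positions) -> svg x
        return x0 + pos * plot_w / max(cols.length, 1)

    def sy(val):  # data y (bits) -> svg y
        return y0 + (cols.ordinate_max - val) * plot_h / span

    for i, stack in enumerate(cols.columns):
        gx = sx(i + _X_PAD)
        gw = sx(i + 1 - _X_PAD) - gx
        for seg in stack:
            if seg.height > 0:
                top, bottom = seg.baseline + seg.height, seg.baseline
            else:
                top, bottom = seg.baseline, seg.baseline + seg.height
            gy = sy(top)
            gh = sy(bottom) - gy
            if gh <= 0:
                continue
            svg.path(
                _glyph_path_d(seg.symbol, gx, gy, gw, gh),
                fill=cols.alphabet.color(seg.symbol),
                cls=cls,
                extra=f'data-symbol="{seg.symbol}"',
            )


def _ordinate_ticks(cols: LogoColumns):
    ticks = {cols.ordinate_min, 0.0, cols.ordinate_max}
    return sorted(ticks)


def render_logo_svg(cols: LogoColumns, spec: FigureSpec) -> str:
    """Standalone sequence/difference logo as an SVG string."""
    plot_w = max(cols.length, 1) * spec.column_width
    plot_h = spec.logo_height
    width = spec.margin_left + plot_w + spec.margin_right
    height = spec.margin_top + plot_h + spec.margin_bottom
    svg = _Svg(width, height)
    x0, y0 = spec.margin_left, spec.margin_top
    span = cols.ordinate_max - cols.ordinate_min

    def sy(val):
        return y0 + (cols.ordinate_max - val) * plot_h / span

    # axes
    svg.line(x0, y0, x0, y0 + plot_h, cls="axis")
    base_y = sy(0.0)
    svg.line(x0, base_y, x0 + plot_w, base_y, cls="axis")
    for tick in _ordinate_ticks(cols):
        ty = sy(tick)
        svg.line(x0 - 4, ty, x0, ty, cls="tick")
        svg.text(x0 - 7, ty + spec.font_size * 0.35, format(tick, "g"), spec.font_size * 0.85,
                 anchor="end", cls="ticklabel")
    for i in range(cols.length):
        cx = x0 + (i + 0.5) * spec.column_width
        svg.text(cx, y0 + plot_h + spec.font_size + 4, str(i + 1), spec.font_size * 0.85,
                 cls="ticklabel")
    svg.text(x0 + plot_w / 2, height - 8, spec.axis_label_x, spec.font_size, cls="axislabel")
    svg.text(14, y0 + plot_h / 2, spec.axis_label_y, spec.font_size, cls="axislabel", rotate=-90)

    _draw_columns(svg, cols, x0, y0, plot_w, plot_h)
    return svg.tostring()


def _tree_segments(grid: ComparisonGrid):
    """Dendrogram line segments in (leaf-slot, height) coordinates.

    Leaf slot i is the center of ordered column i; heights are merge
    heights.  Valid because the leaf ordering keeps every subtree's leaves
    contiguous.
    """
    slot = {lab: i for i, lab in enumerate(grid.ordering)}
    segments = []

    def walk(node):
        if node.is_leaf:
            return slot[node.label], 0.0
        xl, hl = walk(node.left)
        xr, hr = walk(node.right)
        h = node.height
        segments.append(((xl, hl), (xl, h)))
        segments.append(((xr, hr), (xr, h)))
        segments.append(((xl, h), (xr, h)))
        return (xl + xr) / 2.0, h

    walk(grid.tree.root)
    return segments


def render_grid_svg(
    grid: ComparisonGrid,
    spec: FigureSpec,
    show_header_logos: bool = True,
    show_tree: bool = True,
) -> str:
    """N x N comparison grid as an SVG string.

    Layout, top to bottom: cluster dendrogram, sequence logos of the ordered
    motifs, column name labels, then the cell matrix with row name labels on
    the left.  Cell (i, j) holds the difference logo of ordered motif i
    (rows) against ordered motif j (columns) on the shared ordinate, over a
    background rectangle colored by D.
    """
    n = grid.n
    left_band = 64.0
    tree_h = spec.tree_band if show_tree else 0.0
    header_h = spec.header_logo_band if show_header_logos else 0.0
    top = spec.margin_top + tree_h + header_h + spec.label_band
    width = left_band + n * spec.cell_width + (n - 1) * spec.cell_gap + spec.margin_right
    height = top + n * spec.cell_height + (n - 1) * spec.cell_gap + spec.margin_bottom
    svg = _Svg(width, height)

    def cell_x(j):
        return left_band + j * (spec.cell_width + spec.cell_gap)

    def cell_y(i):
        return top + i * (spec.cell_height + spec.cell_gap)

    # dendrogram band
    if show_tree and grid.tree.root.height > 0:
        hmax = grid.tree.root.height
        ty0 = spec.margin_top

        def px(x):
            return left_band + x * (spec.cell_width + spec.cell_gap) + spec.cell_width / 2

        def py(h):
            return ty0 + (1 - h / hmax) * (tree_h - 6)

        for (xa, ha), (xb, hb) in _tree_segments(grid):
            svg.line(px(xa), py(ha), px(xb), py(hb), stroke="#444444", cls="tree")

    # header sequence logos
    if show_header_logos:
        hy = spec.margin_top + tree_h
        for j, logo in enumerate(grid.header_logos):
            _draw_columns(svg, logo, cell_x(j), hy + 2, spec.cell_width, header_h - 8,
                          cls="glyph headerlogo")

    # motif name labels: above each column, left of each row
    ly = spec.margin_top + tree_h + header_h + spec.label_band - 6
    for j, lab in enumerate(grid.ordering):
        svg.text(cell_x(j) + spec.cell_width / 2, ly, lab, spec.font_size, cls="collabel")
    for i, lab in enumerate(grid.ordering):
        svg.text(left_band - 8, cell_y(i) + spec.cell_height / 2 + spec.font_size * 0.35,
                 lab, spec.font_size, anchor="end", cls="rowlabel")

    # cells
    scale = grid.shared_ordinate if grid.shared_ordinate > 0 else 1.0
    for i in range(n):
        for j in range(n):
            x, y = cell_x(j), cell_y(i)
            if i == j:
                continue
            cell = grid.cells[(i, j)]
            svg.rect(x, y, spec.cell_width, spec.cell_height, fill=cell.color, cls="cellbg")
            svg.line(x, y + spec.cell_height / 2, x + spec.cell_width, y + spec.cell_height / 2,
                     stroke="#FFFFFF", width=0.5, cls="zeroline")
            shared = LogoColumns(
                kind="difference",
                columns=cell.geometry.columns,
                ordinate_max=scale,
                ordinate_min=-scale,
                alphabet=cell.geometry.alphabet,
                label=cell.geometry.label,
            )
            _draw_columns(svg, shared, x, y, spec.cell_width, spec.cell_height)
    return svg.tostring()


def _render_columns_mpl(ax, cols: LogoColumns):
    from matplotlib.patches import Rectangle

    for i, stack in enumerate(cols.columns):
        for seg in stack:
            lo = min(seg.baseline, seg.baseline + seg.height)
            hi = max(seg.baseline, seg.baseline + seg.height)
            color = cols.alphabet.color(seg.symbol)
            for rx, ry, rw, rh in glyph_rects(seg.symbol):
                # glyph y runs downward; flip into data coordinates
                gy = hi - (ry + rh) * (hi - lo)
                ax.add_patch(
                    Rectangle(
                        (i + _X_PAD + rx * (1 - 2 * _X_PAD), gy),
                        rw * (1 - 2 * _X_PAD),
                        rh * (hi - lo),
                        facecolor=color,
                        edgecolor="none",
                    )
                )


def _render_logo_mpl(cols: LogoColumns, spec: FigureSpec, path: str):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(cols.length, 1) * spec.column_width / 72, (spec.logo_height + 60) / 72)
    )
    _render_columns_mpl(ax, cols)
    ax.set_xlim(0, max(cols.length, 1))
    ax.set_ylim(cols.ordinate_min, cols.ordinate_max)
    if cols.ordinate_min < 0:
        ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xticks([i + 0.5 for i in range(cols.length)])
    ax.set_xticklabels([str(i + 1) for i in range(cols.length)])
    ax.set_xlabel(spec.axis_label_x)
    ax.set_ylabel(spec.axis_label_y)
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)


def _render_grid_mpl(grid: ComparisonGrid, spec: FigureSpec, path: str,
                     show_header_logos: bool, show_tree: bool):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = grid.n
    extra = int(show_header_logos) + int(show_tree)
    fig, axes = plt.subplots(
        n + extra, n,
        figsize=(n * spec.cell_width / 72, (n + extra) * spec.cell_height / 72),
        squeeze=False,
    )
    row0 = 0
    if show_tree:
        for j in range(n):
            axes[0][j].axis("off")
        hmax = grid.tree.root.height or 1.0
        axt = fig.add_axes([0.05, 1 - 0.9 / (n + extra), 0.9, 0.8 / (n + extra)])
        for (xa, ha), (xb, hb) in _tree_segments(grid):
            axt.plot([xa, xb], [ha, hb], color="#444444", linewidth=1.0)
        axt.set_xlim(-0.5, n - 0.5)
        axt.set_ylim(0, hmax * 1.05)
        axt.axis("off")
        row0 += 1
    if show_header_logos:
        for j, logo in enumerate(grid.header_logos):
            ax = axes[row0][j]
            _render_columns_mpl(ax, logo)
            ax.set_xlim(0, max(logo.length, 1))
            ax.set_ylim(0, logo.ordinate_max)
            ax.set_xticks([])
            ax.set_yticks([])
        row0 += 1
    scale = grid.shared_ordinate if grid.shared_ordinate > 0 else 1.0
    for i in range(n):
        for j in range(n):
            ax = axes[row0 + i][j]
            ax.set_xticks([])
            ax.set_yticks([])
            if i == j:
                ax.axis("off")
                continue
            cell = grid.cells[(i, j)]
            ax.set_facecolor(cell.color)
            _render_columns_mpl(ax, cell.geometry)
            ax.set_xlim(0, max(cell.geometry.length, 1))
            ax.set_ylim(-scale, scale)
            ax.axhline(0.0, color="white", linewidth=0.5)
            if i == n - 1:
                ax.set_xlabel(grid.ordering[j], fontsize=8)
            if j == 0:
                ax.set_ylabel(grid.ordering[i], fontsize=8)
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)


def _format_of(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext not in ("svg", "png", "pdf"):
        raise MotifError(f"unsupported output format {ext!r} (svg, png, pdf)")
    return ext


def render_logo(cols: LogoColumns, spec: FigureSpec, path) -> None:
    """Render a logo to ``path``; format chosen by extension (.svg/.png/.pdf)."""
    fmt = _format_of(path)
    if fmt == "svg":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_logo_svg(cols, spec))
    else:
        _render_logo_mpl(cols, spec, str(path))


def render_grid(
    grid: ComparisonGrid,
    spec: FigureSpec,
    path,
    show_header_logos: bool = True,
    show_tree: bool = True,
) -> None:
    """Render a comparison grid to ``path`` (.svg/.png/.pdf)."""
    fmt = _format_of(path)
    if fmt == "svg":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_grid_svg(grid, spec, show_header_logos, show_tree))
    else:
        _render_grid_mpl(grid, spec, str(path), show_header_logos, show_tree)
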