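"""Deterministic 2D layout and SVG depiction of glycan documents.

SNFG orientation: the reducing end (core root) is drawn rightmost and the
tree grows leftward. Among siblings, the branch on the *larger* known
parent position is drawn on the upper row; branches with unknown positions
go below known ones; ties break by creation order. Fragment parts are
drawn strictly left of a single right-facing square bracket, which itself
lies strictly left of the core's bounding box. When a fragment's candidate
attachment sites are a proper subset of the core, its "*n" number is drawn
on the fragment's pending edge and on each selected core residue; when
every core residue is a candidate the numbers are suppressed.

``render_svg`` is a pure function of (document, options): equal inputs
yield byte-identical SVG 1.1 text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional
from xml.sax.saxutils import escape

from . import snfg
from .model import GlycanDocument, GlycanTree, Linkage
from .snfg import UNKNOWN, SNFGSymbol


@dataclass(frozen=True)
class RenderOptions:
    spacing: float = 50.0   # grid unit, px
    radius: float = 18.0    # symbol half-size, px
    padding: float = 40.0
    font_size: float = 11.0


@dataclass
class LayoutNode:
    """A residue placed on the layout grid."""

    residue_id: int
    part_index: int               # 0 = core, n = fragment index
    col: float                    # increases leftward from the root
    row: float
    x: float = 0.0
    y: float = 0.0
    symbol: Optional[SNFGSymbol] = None
    annotations: tuple[str, ...] = ()


def assign_symbol(residue) -> SNFGSymbol:
    """SNFG symbol for a residue: dictionary lookup with a generic
    white-shape fallback for unmatched residues."""
    cls = snfg.match_class(
        residue.stems, residue.configs, residue.superclass,
        residue.modifications,
        [(s.position, s.name) for s in residue.substituents],
    )
    if cls is not None:
        return cls.symbol
    return snfg.generic_symbol(residue.superclass)


def _layout_tree(tree: GlycanTree) -> dict[int, tuple[float, float]]:
    """Tidy layout: col = depth, leaf rows sequential from the top,
    internal rows the mean of their children. Sibling order: larger known
    parent position first (upper), unknown positions below known."""
    pos: dict[int, tuple[float, float]] = {}
    next_row = [0.0]

    def order_children(rid: int) -> list[Linkage]:
        def key(ln: Linkage):
            known = [p for p in ln.parent_positions if p != UNKNOWN]
            # negative position => descending; unknowns sort after knowns
            return (not known, -(max(known) if known else 0), ln.child_id)
        return sorted(tree.child_linkages(rid), key=key)

    def visit(rid: int, depth: float) -> float:
        children = order_children(rid)
        if not children:
            row = next_row[0]
            next_row[0] += 1.0
        else:
            rows = [visit(ln.child_id, depth + 1) for ln in children]
            row = sum(rows) / len(rows)
        pos[rid] = (depth, row)
        return row

    if tree.root_id is not None:
        visit(tree.root_id, 0.0)
    return pos


def layout(doc: GlycanDocument,
           options: RenderOptions = RenderOptions()) -> list[LayoutNode]:
    """Place every residue of the document on the pixel grid."""
    nodes: list[LayoutNode] = []
    core_pos = _layout_tree(doc.core)
    frags = sorted(doc.fragments, key=lambda f: f.index)

    core_max_col = max((c for c, _ in core_pos.values()), default=0.0)
    core_max_row = max((r for _, r in core_pos.values()), default=0.0)

    frag_layouts = []
    frag_row_base = 0.0
    frag_max_width = 0.0
    for frag in frags:
        fpos = _layout_tree(frag.tree)
        height = max(r for _, r in fpos.values()) + 1.0
        width = max(c for c, _ in fpos.values())
        frag_max_width = max(frag_max_width, width)
        frag_layouts.append((frag, fpos, frag_row_base))
        frag_row_base += height
    # fragments sit left of the bracket: bracket column is core_max_col + 1,
    # fragment roots start at core_max_col + 2
    bracket_col = core_max_col + 1.0 if frags else None
    total_cols = core_max_col + (2.0 + frag_max_width if frags else 0.0)

    def to_px(col: float, row: float) -> tuple[float, float]:
        x = options.padding + (total_cols - col) * options.spacing
        y = options.padding + row * options.spacing
        return x, y

    annotations_by_core: dict[int, list[str]] = {}
    for frag in frags:
        if not frag.sites_complete(doc.core):
            for rid in frag.attachment_sites:
                annotations_by_core.setdefault(rid, []).append(
                    f"*{frag.index}"
                )

    for rid, (col, row) in sorted(core_pos.items()):
        x, y = to_px(col, row)
        nodes.append(LayoutNode(
            residue_id=rid, part_index=0, col=col, row=row, x=x, y=y,
            symbol=assign_symbol(doc.core.residues[rid]),
            annotations=tuple(sorted(annotations_by_core.get(rid, ()))),
        ))
    for frag, fpos, row_base in frag_layouts:
        show = not frag.sites_complete(doc.core)
        for rid, (col, row) in sorted(fpos.items()):
            gcol = core_max_col + 2.0 + col
            grow = row + row_base
            x, y = to_px(gcol, grow)
            ann = ()
            if show and rid == frag.tree.root_id:
                ann = (f"*{frag.index}",)
            nodes.append(LayoutNode(
                residue_id=rid, part_index=frag.index,
                col=gcol, row=grow, x=x, y=y,
                symbol=assign_symbol(frag.tree.residues[rid]),
                annotations=ann,
            ))
    return nodes


# ---------------------------------------------------------------------------
# SVG emission

_GREEK = {"a": "α", "b": "β", "o": "", "x": "?"}


def _fmt(v: float) -> str:
    return f"{v:.1f}"


def _linkage_label(anomer: str, positions: tuple[int, ...]) -> str:
    pos = "|".join("?" if p == UNKNOWN else str(p) for p in positions)
    return f"{_GREEK.get(anomer, '?')}{pos}"


def _shape_element(symbol: SNFGSymbol, x: float, y: float,
                   r: float) -> list[str]:
    """SVG elements for one symbol; the first carries class snfg-symbol."""
    fill = symbol.color_hex
    common = f'fill="{fill}" stroke="#000000" stroke-width="1.5"'
    out: list[str] = []

    def poly(points: list[tuple[float, float]], cls: str,
             fill_override: Optional[str] = None) -> str:
        pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in points)
        f = fill_override or fill
        return (f'<polygon class="{cls}" points="{pts}" fill="{f}" '
                f'stroke="#000000" stroke-width="1.5" />')

    shape = symbol.shape
    if shape == "circle":
        out.append(f'<circle class="snfg-symbol" cx="{_fmt(x)}" '
                   f'cy="{_fmt(y)}" r="{_fmt(r)}" {common} />')
    elif shape in ("square", "crossed_square"):
        s = r * 1.7
        out.append(f'<rect class="snfg-symbol" x="{_fmt(x - s / 2)}" '
                   f'y="{_fmt(y - s / 2)}" width="{_fmt(s)}" '
                   f'height="{_fmt(s)}" {common} />')
        if shape == "crossed_square":
            out.append(poly(
                [(x - s / 2, y - s / 2), (x + s / 2, y - s / 2),
                 (x - s / 2, y + s / 2)],
                "snfg-half", "#FFFFFF"))
    elif shape == "rectangle":
        s = r * 1.7
        out.append(f'<rect class="snfg-symbol" x="{_fmt(x - s / 2)}" '
                   f'y="{_fmt(y - s / 4)}" width="{_fmt(s)}" '
                   f'height="{_fmt(s / 2)}" {common} />')
    elif shape in ("triangle", "divided_triangle"):
        pts = [(x, y - r), (x + r, y + r * 0.8), (x - r, y + r * 0.8)]
        out.append(poly(pts, "snfg-symbol"))
        if shape == "divided_triangle":
            out.append(poly([(x, y - r), (x + r, y + r * 0.8),
                             (x, y + r * 0.8)], "snfg-half", "#FFFFFF"))
    elif shape in ("diamond", "divided_diamond"):
        pts = [(x, y - r), (x + r, y), (x, y + r), (x - r, y)]
        out.append(poly(pts, "snfg-symbol"))
        if shape == "divided_diamond":
            out.append(poly([(x, y - r), (x + r, y), (x - r, y)],
                            "snfg-half", "#FFFFFF"))
    elif shape == "star":
        pts = []
        for i in range(10):
            rr = r if i % 2 == 0 else r * 0.45
            ang = -math.pi / 2 + i * math.pi / 5
            pts.append((x + rr * math.cos(ang), y + rr * math.sin(ang)))
        out.append(poly(pts, "snfg-symbol"))
    else:  # pragma: no cover - dictionary shapes are closed
        out.append(f'<circle class="snfg-symbol" cx="{_fmt(x)}" '
                   f'cy="{_fmt(y)}" r="{_fmt(r)}" {common} />')
    return out


def render_svg(doc: GlycanDocument,
               options: RenderOptions = RenderOptions()) -> str:
    """Render a document to SVG 1.1 text.

    One ``snfg-symbol`` shape per residue, one ``linkage`` line per bond,
    one ``bracket`` path per fragment-bearing document, ``annotation``
    text elements for "*n" marks and ``linkage-label`` texts for
    anomer/position strings.
    """
    nodes = layout(doc, options)
    by_id = {n.residue_id: n for n in nodes}
    opt = options

    frags = sorted(doc.fragments, key=lambda f: f.index)
    elements: list[str] = []

    # linkage lines first so symbols draw over them
    def edge(tree: GlycanTree, part_is_core: bool) -> None:
        for ln in tree.linkages:
            a = by_id[ln.parent_id]
            b = by_id[ln.child_id]
            elements.append(
                f'<line class="linkage" x1="{_fmt(a.x)}" y1="{_fmt(a.y)}" '
                f'x2="{_fmt(b.x)}" y2="{_fmt(b.y)}" stroke="#000000" '
                f'stroke-width="1.5" />'
            )
            anomer = tree.residues[ln.child_id].anomer
            label = _linkage_label(anomer, ln.parent_positions)
            lx = a.x + (b.x - a.x) * 0.35
            ly = a.y + (b.y - a.y) * 0.35 - 4.0
            elements.append(
                f'<text class="linkage-label" x="{_fmt(lx)}" '
                f'y="{_fmt(ly)}" font-size="{_fmt(opt.font_size)}">'
                f"{escape(label)}</text>"
            )

    edge(doc.core, True)
    for frag in frags:
        edge(frag.tree, False)

    core_nodes = [n for n in nodes if n.part_index == 0]
    bracket_x = None
    if frags and core_nodes:
        min_core_x = min(n.x for n in core_nodes)
        bracket_x = min_core_x - opt.spacing
        ys = [n.y for n in nodes]
        top = min(ys) - opt.spacing * 0.5
        bot = max(ys) + opt.spacing * 0.5
        tick = opt.spacing * 0.25
        elements.append(
            f'<path class="bracket" d="M {_fmt(bracket_x + tick)} '
            f'{_fmt(top)} L {_fmt(bracket_x)} {_fmt(top)} '
            f'L {_fmt(bracket_x)} {_fmt(bot)} '
            f'L {_fmt(bracket_x + tick)} {_fmt(bot)}" fill="none" '
            f'stroke="#000000" stroke-width="2.0" />'
        )
        # pending edge from each fragment root toward the bracket
        for frag in frags:
            root = by_id[frag.tree.root_id]
            li = frag.linkage_info
            anomer = frag.tree.residues[frag.tree.root_id].anomer
            elements.append(
                f'<line class="fragment-edge" x1="{_fmt(root.x)}" '
                f'y1="{_fmt(root.y)}" x2="{_fmt(bracket_x)}" '
                f'y2="{_fmt(root.y)}" stroke="#000000" stroke-width="1.5" '
                f'stroke-dasharray="4,3" />'
            )
            label = _linkage_label(anomer, li.parent_positions)
            elements.append(
                f'<text class="linkage-label" '
                f'x="{_fmt((root.x + bracket_x) / 2)}" '
                f'y="{_fmt(root.y - 6.0)}" '
                f'font-size="{_fmt(opt.font_size)}">'
                f"{escape(label)}</text>"
            )

    for node in nodes:
        assert node.symbol is not None
        elements.extend(
            _shape_element(node.symbol, node.x, node.y, opt.radius)
        )
        res = doc.residue(node.residue_id)
        if node.symbol.color == "white":
            # generic fallback: print the label inside the shape
            elements.append(
                f'<text class="label" x="{_fmt(node.x)}" '
                f'y="{_fmt(node.y + 3.0)}" text-anchor="middle" '
                f'font-size="{_fmt(opt.font_size * 0.9)}">'
                f"{escape(node.symbol.label)}</text>"
            )
        # unfused substituents as short text (e.g. "6S")
        cls = snfg.match_class(
            res.stems, res.configs, res.superclass, res.modifications,
            [(s.position, s.name) for s in res.substituents],
        )
        fused = set(cls.subs) if cls is not None else set()
        extra = [
            s for s in res.sorted_substituents()
            if (s.position, s.name) not in fused
        ]
        for i, sub in enumerate(extra):
            short = snfg.substituent_class(sub.name).short
            pos = "?" if sub.position == UNKNOWN else str(sub.position)
            elements.append(
                f'<text class="substituent" x="{_fmt(node.x)}" '
                f'y="{_fmt(node.y + opt.radius + 12.0 + i * 11.0)}" '
                f'text-anchor="middle" '
                f'font-size="{_fmt(opt.font_size * 0.9)}">'
                f"{escape(pos + short)}</text>"
            )
        for i, ann in enumerate(node.annotations):
            elements.append(
                f'<text class="annotation" '
                f'x="{_fmt(node.x + opt.radius + 2.0)}" '
                f'y="{_fmt(node.y - opt.radius + i * 11.0)}" '
                f'font-size="{_fmt(opt.font_size)}">'
                f"{escape(ann)}</text>"
            )

    if nodes:
        width = max(n.x for n in nodes) + opt.padding
        height = max(n.y for n in nodes) + opt.padding
    else:
        width = height = 2 * opt.padding
    header = (
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    return "\n".join([header] + elements + ["</svg>"]) + "\n"
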