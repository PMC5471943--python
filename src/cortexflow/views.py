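"""Static SVG rendering: alluvial timeline, K-likelihood heatmap, glyphs.

All rendering here is a pure function of its inputs: element order is
fixed, coordinates are emitted at two decimals, and identical inputs give
byte-identical SVG.  Three views are produced:

* the *alluvial* cluster-evolution view — per timestep a vertical stack of
  blocks (height proportional to cluster size, solid community color)
  joined by cubic Bezier ribbons whose thickness encodes electrode flow;
* the *K-cluster heatmap* — one grayscale cell per (timestep, candidate K)
  where black is high likelihood and white low;
* the *electrode views* — per aggregation span, a spatial panel of clock
  glyphs (one slice per timestep, clockwise from 12 o'clock, color =
  community, opacity = activation), panels alternating above and below a
  central alluvial band with widths from the expansion-factor model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .data_io import ActivationSeries, ElectrodeLayout, ValidationError
from .ordering import TimelineOrdering
from .tracking import DynamicCommunitySet


class LayoutInfeasibleError(ValueError):
    """Raised when the expansion-factor constraint S_f >= 1 cannot hold."""


# ---------------------------------------------------------------------------
# Width model
# ---------------------------------------------------------------------------

def expansion_factor(
    n_x1: int, n_x2: int, w_max: float, w_min: float, c: float
) -> tuple[float, float]:
    """Expansion factor and per-view width of the electrode-view layout.

    ``S_f = C * W_max / (w_min * max(N_x1, N_x2))`` and ``w_i = w_min * S_f``
    with the constraint ``S_f >= 1``; on violation the error names the
    largest feasible minimal width.
    """
    if w_max <= 0 or w_min <= 0 or c <= 0:
        raise ValueError("W_max, w_min and C must be positive")
    n_views = max(n_x1, n_x2)
    if n_views < 1:
        raise ValueError("need at least one electrode view")
    s_f = c * w_max / (w_min * n_views)
    if s_f < 1.0:
        feasible = c * w_max / n_views
        raise LayoutInfeasibleError(
            f"S_f = {s_f:.4g} < 1; reduce w_min to at most {feasible:.4g}"
        )
    return s_f, w_min * s_f


@dataclass
class LayoutSpec:
    """Resolved width model for a composed electrode-view figure."""

    w_max: float
    w_min: float
    c: float
    n_x1: int
    n_x2: int
    s_f: float
    w_i: float

    @classmethod
    def from_params(
        cls, n_x1: int, n_x2: int, w_max: float, w_min: float, c: float
    ) -> "LayoutSpec":
        s_f, w_i = expansion_factor(n_x1, n_x2, w_max, w_min, c)
        return cls(w_max=w_max, w_min=w_min, c=c, n_x1=n_x1, n_x2=n_x2, s_f=s_f, w_i=w_i)


@dataclass(frozen=True)
class ViewPlan:
    """One electrode view: its timestep span and which axis it sits on."""

    index: int
    span: tuple[int, int]  # half-open [a, b)
    axis: Literal["x1", "x2"]


def plan_views(t_total: int, granularity: int) -> list[ViewPlan]:
    """Partition the timeline into aggregation spans, alternating axes.

    Spans are consecutive half-open windows of ``granularity`` timesteps
    (the last may be shorter); views alternate above (x1) and below (x2)
    the evolution view, left to right in time order.
    """
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    if granularity > t_total:
        raise ValueError("granularity exceeds number of timesteps")
    plans = []
    for k, a in enumerate(range(0, t_total, granularity)):
        b = min(a + granularity, t_total)
        plans.append(ViewPlan(index=k, span=(a, b), axis="x1" if k % 2 == 0 else "x2"))
    return plans


# ---------------------------------------------------------------------------
# Glyphs
# ---------------------------------------------------------------------------

@dataclass
class GlyphSpec:
    """Clock glyph: one (color, opacity) slice per aggregated timestep,
    clockwise from the top."""

    slices: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("glyph needs at least one slice")
        for _, op in self.slices:
            if not 0.0 <= op <= 1.0:
                raise ValueError("slice opacity outside [0, 1]")


def aggregate_glyphs(
    dcs: DynamicCommunitySet,
    activation: ActivationSeries,
    span: tuple[int, int],
) -> dict[str, GlyphSpec]:
    """Per-electrode glyph for one aggregation span.

    Slice k shows timestep ``span[0] + k``: its color is the persistent
    community the electrode belongs to then, its opacity that timestep's
    activation.
    """
    a, b = span
    if not (0 <= a < b <= dcs.n_timesteps):
        raise ValueError(f"span {span} outside [0, {dcs.n_timesteps})")
    if activation.values.shape != (len(dcs.node_ids), dcs.n_timesteps):
        raise ValidationError("activation shape does not match community set")
    node_index = {n: k for k, n in enumerate(dcs.node_ids)}
    color_at: list[dict[str, str]] = []
    for t in range(a, b):
        cmap = {}
        for block in dcs.blocks[t]:
            col = dcs.colors[block.persistent_id]
            for n in block.members:
                cmap[n] = col
        color_at.append(cmap)
    return {
        n: GlyphSpec(
            [
                (color_at[t - a][n], float(activation.values[node_index[n], t]))
                for t in range(a, b)
            ]
        )
        for n in dcs.node_ids
    }


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _slice_path(cx: float, cy: float, r: float, n: int, k: int) -> str:
    """Wedge k of n, clockwise from 12 o'clock (SVG screen coordinates)."""
    th0 = 2.0 * math.pi * k / n
    th1 = 2.0 * math.pi * (k + 1) / n
    x0, y0 = cx + r * math.sin(th0), cy - r * math.cos(th0)
    x1, y1 = cx + r * math.sin(th1), cy - r * math.cos(th1)
    return (
        f"M {_fmt(cx)},{_fmt(cy)} L {_fmt(x0)},{_fmt(y0)} "
        f"A {_fmt(r)},{_fmt(r)} 0 0 1 {_fmt(x1)},{_fmt(y1)} Z"
    )


def glyph_svg(cx: float, cy: float, r: float, glyph: GlyphSpec) -> str:
    """SVG group for one clock glyph (outline always visible)."""
    n = len(glyph.slices)
    parts = ["<g>"]
    for k, (color, opacity) in enumerate(glyph.slices):
        if n == 1:
            parts.append(
                f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
                f'fill="{color}" fill-opacity="{_fmt(opacity)}"/>'
            )
        else:
            parts.append(
                f'<path d="{_slice_path(cx, cy, r, n, k)}" fill="{color}" '
                f'fill-opacity="{_fmt(opacity)}"/>'
            )
    parts.append(
        f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
        f'fill="none" stroke="#555555" stroke-width="0.50"/>'
    )
    parts.append("</g>")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Alluvial view
# ---------------------------------------------------------------------------

def alluvial_scene(
    dcs: DynamicCommunitySet,
    ordering: TimelineOrdering,
    width: float = 800.0,
    height: float = 400.0,
    margin: float = 10.0,
    block_width: float = 12.0,
) -> dict:
    """Geometry of the alluvial view: block rectangles and ribbon paths.

    Block heights are proportional to cluster size (the per-timestep
    heights always sum to |N| height units); ribbons are cubic Beziers with
    control points at the horizontal midpoint between consecutive columns.
    """
    if width <= 0 or height <= 0:
        raise ValueError("zero-size canvas")
    t_total = dcs.n_timesteps
    n = len(dcs.node_ids)
    unit = (height - 2 * margin) / n
    inner = width - 2 * margin - block_width
    xs = [
        margin + block_width / 2 + (t * inner / (t_total - 1) if t_total > 1 else inner / 2)
        for t in range(t_total)
    ]

    sizes = [{b.i: len(b.members) for b in blocks} for blocks in dcs.blocks]
    tops: list[dict[int, float]] = []
    rects = []
    for t, blocks in enumerate(dcs.blocks):
        top: dict[int, float] = {}
        y = margin
        for i in ordering.permutations[t]:
            top[i] = y
            y += sizes[t][i] * unit
        tops.append(top)
        for b in blocks:
            rects.append(
                {
                    "t": t,
                    "i": b.i,
                    "persistent_id": b.persistent_id,
                    "x": xs[t] - block_width / 2,
                    "y": top[b.i],
                    "w": block_width,
                    "h": sizes[t][b.i] * unit,
                    "color": dcs.colors[b.persistent_id],
                }
            )

    ribbons = []
    for t, links in enumerate(dcs.links):
        out_off: dict[int, float] = {i: 0.0 for i in sizes[t]}
        in_off: dict[int, float] = {j: 0.0 for j in sizes[t + 1]}
        # allocate source-edge segments in sink-position order and vice versa
        for lk in sorted(
            links,
            key=lambda lk: (ordering.position(t, lk.source), ordering.position(t + 1, lk.sink), lk.source, lk.sink),
        ):
            thick = lk.count * unit
            ys = tops[t][lk.source] + out_off[lk.source]
            out_off[lk.source] += thick
            yt = tops[t + 1][lk.sink] + in_off[lk.sink]
            in_off[lk.sink] += thick
            x0 = xs[t] + block_width / 2
            x1 = xs[t + 1] - block_width / 2
            mx = (x0 + x1) / 2
            pid = dcs.blocks[t][lk.source].persistent_id
            path = (
                f"M {_fmt(x0)},{_fmt(ys)} "
                f"C {_fmt(mx)},{_fmt(ys)} {_fmt(mx)},{_fmt(yt)} {_fmt(x1)},{_fmt(yt)} "
                f"L {_fmt(x1)},{_fmt(yt + thick)} "
                f"C {_fmt(mx)},{_fmt(yt + thick)} {_fmt(mx)},{_fmt(ys + thick)} "
                f"{_fmt(x0)},{_fmt(ys + thick)} Z"
            )
            ribbons.append(
                {
                    "t": t,
                    "source": lk.source,
                    "sink": lk.sink,
                    "count": lk.count,
                    "path": path,
                    "color": dcs.colors[pid],
                }
            )
    return {
        "width": width,
        "height": height,
        "unit": unit,
        "rects": rects,
        "ribbons": ribbons,
    }


def _svg_doc(width: float, height: float, body: str) -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        f"{body}\n</svg>\n"
    )


def _alluvial_group(scene: dict) -> str:
    parts = ["<g>"]
    for rb in scene["ribbons"]:
        parts.append(
            f'<path d="{rb["path"]}" fill="{rb["color"]}" fill-opacity="0.50"/>'
        )
    for rc in scene["rects"]:
        parts.append(
            f'<rect x="{_fmt(rc["x"])}" y="{_fmt(rc["y"])}" '
            f'width="{_fmt(rc["w"])}" height="{_fmt(rc["h"])}" '
            f'fill="{rc["color"]}"/>'
        )
    parts.append("</g>")
    return "".join(parts)


def render_alluvial(
    dcs: DynamicCommunitySet,
    ordering: TimelineOrdering,
    width: float = 800.0,
    height: float = 400.0,
) -> str:
    """Standalone SVG of the cluster-evolution (alluvial) view."""
    scene = alluvial_scene(dcs, ordering, width=width, height=height)
    return _svg_doc(width, height, _alluvial_group(scene))


# ---------------------------------------------------------------------------
# K-cluster heatmap
# ---------------------------------------------------------------------------

def heatmap_scene(
    profiles: Sequence[dict[int, float]],
    cell: float = 14.0,
    margin: float = 2.0,
) -> dict:
    """Grid geometry of the K-likelihood heatmap (x = timestep, y = K)."""
    if not profiles:
        raise ValueError("no likelihood profiles")
    k_range = sorted(profiles[0])
    for p in profiles:
        if sorted(p) != k_range:
            raise ValueError("likelihood profiles do not share one K range")
    cells = []
    for t, prof in enumerate(profiles):
        for row, k in enumerate(k_range):
            lik = prof[k]
            g = int(round(255 * (1.0 - lik)))
            cells.append(
                {
                    "t": t,
                    "k": k,
                    "x": margin + t * cell,
                    "y": margin + row * cell,
                    "fill": f"#{g:02x}{g:02x}{g:02x}",
                    "likelihood": lik,
                }
            )
    return {
        "width": 2 * margin + len(profiles) * cell,
        "height": 2 * margin + len(k_range) * cell,
        "cell": cell,
        "k_range": k_range,
        "cells": cells,
    }


def render_k_heatmap(profiles: Sequence[dict[int, float]], cell: float = 14.0) -> str:
    """SVG heatmap of per-timestep K likelihoods; black = likely, white = not."""
    scene = heatmap_scene(profiles, cell=cell)
    parts = ["<g>"]
    for c in scene["cells"]:
        parts.append(
            f'<rect x="{_fmt(c["x"])}" y="{_fmt(c["y"])}" '
            f'width="{_fmt(scene["cell"])}" height="{_fmt(scene["cell"])}" '
            f'fill="{c["fill"]}" stroke="#cccccc" stroke-width="0.25"/>'
        )
    parts.append("</g>")
    return _svg_doc(scene["width"], scene["height"], "".join(parts))


# ---------------------------------------------------------------------------
# Composed electrode views
# ---------------------------------------------------------------------------

def _map_coordinates(
    layout: ElectrodeLayout,
    node_ids: Sequence[str],
    box: tuple[float, float, float, float],
    pad_fraction: float = 0.12,
) -> dict[str, tuple[float, float]]:
    """Affine map of (optionally cropped) electrode coordinates into a view
    box, uniform scale, centered — relative distances are preserved."""
    layout.check_covers(node_ids)
    pts = {n: layout.coordinates[n] for n in node_ids}
    if layout.crop_region is not None:
        xmin, ymin, xmax, ymax = layout.crop_region
    else:
        xs = [p[0] for p in pts.values()]
        ys = [p[1] for p in pts.values()]
        xmin, xmax = min(xs), max(xs)
        ymin, ymax = min(ys), max(ys)
    bx, by, bw, bh = box
    pad = pad_fraction * min(bw, bh)
    cw = max(xmax - xmin, 1e-12)
    ch = max(ymax - ymin, 1e-12)
    s = min((bw - 2 * pad) / cw, (bh - 2 * pad) / ch)
    ox = bx + (bw - s * cw) / 2
    oy = by + (bh - s * ch) / 2
    return {n: (ox + s * (x - xmin), oy + s * (y - ymin)) for n, (x, y) in pts.items()}


def _glyph_radius(mapped: dict[str, tuple[float, float]], box_w: float, box_h: float) -> float:
    pts = list(mapped.values())
    if len(pts) < 2:
        return min(box_w, box_h) / 6.0
    arr = np.asarray(pts)
    d2 = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    dmin = math.sqrt(float(d2.min()))
    return min(0.45 * dmin, min(box_w, box_h) / 6.0)


def electrode_scene(
    views: Sequence[tuple[ViewPlan, dict[str, GlyphSpec]]],
    layout: ElectrodeLayout,
    layout_spec: LayoutSpec,
    view_height: Optional[float] = None,
    band_height: float = 120.0,
    margin: float = 10.0,
) -> dict:
    """Geometry of the composed figure: panels alternating above/below a
    central band, x-offsets the cumulative sums of view widths; view width
    shares are proportional to span length when spans are unequal."""
    if not views:
        raise ValueError("no electrode views")
    base_span = max(plan.span[1] - plan.span[0] for plan, _ in views)
    widths = [
        layout_spec.w_i * (plan.span[1] - plan.span[0]) / base_span for plan, _ in views
    ]
    vh = view_height if view_height is not None else layout_spec.w_i
    x_offsets = [margin + float(sum(widths[:k])) for k in range(len(widths))]
    total_w = 2 * margin + sum(widths)
    total_h = 2 * margin + 2 * vh + band_height
    panels = []
    for (plan, glyphs), w, x in zip(views, widths, x_offsets):
        y = margin if plan.axis == "x1" else margin + vh + band_height
        node_ids = sorted(glyphs)
        mapped = _map_coordinates(layout, node_ids, (x, y, w, vh))
        r = _glyph_radius(mapped, w, vh)
        panels.append(
            {
                "index": plan.index,
                "span": list(plan.span),
                "axis": plan.axis,
                "x": x,
                "y": y,
                "w": w,
                "h": vh,
                "radius": r,
                "glyphs": [
                    {
                        "id": n,
                        "cx": mapped[n][0],
                        "cy": mapped[n][1],
                        "slices": list(glyphs[n].slices),
                    }
                    for n in node_ids
                ],
            }
        )
    return {
        "width": total_w,
        "height": total_h,
        "band": {"x": margin, "y": margin + vh, "w": total_w - 2 * margin, "h": band_height},
        "panels": panels,
    }


def render_electrode_views(
    views: Sequence[tuple[ViewPlan, dict[str, GlyphSpec]]],
    layout: ElectrodeLayout,
    layout_spec: LayoutSpec,
    dcs: Optional[DynamicCommunitySet] = None,
    ordering: Optional[TimelineOrdering] = None,
    view_height: Optional[float] = None,
    band_height: float = 120.0,
) -> str:
    """SVG of the composed electrode-view figure.

    When a tracked community set and ordering are supplied, the central
    band carries the alluvial view synchronized with the timeline;
    otherwise it is an empty strip.  An optional raster underlay referenced
    by the layout is drawn beneath each panel.
    """
    scene = electrode_scene(
        views, layout, layout_spec, view_height=view_height, band_height=band_height
    )
    parts = ["<g>"]
    band = scene["band"]
    parts.append(
        f'<rect x="{_fmt(band["x"])}" y="{_fmt(band["y"])}" '
        f'width="{_fmt(band["w"])}" height="{_fmt(band["h"])}" '
        f'fill="#f7f7f7" stroke="#dddddd" stroke-width="0.50"/>'
    )
    if dcs is not None and ordering is not None:
        sub = alluvial_scene(
            dcs, ordering, width=band["w"], height=band["h"], margin=4.0
        )
        parts.append(
            f'<g transform="translate({_fmt(band["x"])},{_fmt(band["y"])})">'
            + _alluvial_group(sub)
            + "</g>"
        )
    for panel in scene["panels"]:
        parts.append(
            f'<rect x="{_fmt(panel["x"])}" y="{_fmt(panel["y"])}" '
            f'width="{_fmt(panel["w"])}" height="{_fmt(panel["h"])}" '
            f'fill="none" stroke="#bbbbbb" stroke-width="0.50"/>'
        )
        if layout.background_image is not None:
            parts.append(
                f'<image href="{layout.background_image}" x="{_fmt(panel["x"])}" '
                f'y="{_fmt(panel["y"])}" width="{_fmt(panel["w"])}" '
                f'height="{_fmt(panel["h"])}" preserveAspectRatio="xMidYMid meet" '
                f'opacity="0.35"/>'
            )
        for g in panel["glyphs"]:
            parts.append(
                glyph_svg(g["cx"], g["cy"], panel["radius"], GlyphSpec(list(g["slices"])))
            )
    parts.append("</g>")
    return _svg_doc(scene["width"], scene["height"], "".join(parts))
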