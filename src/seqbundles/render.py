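"""Compositing the Sequence Bundles image, and its streamgraph variant.

A :class:`BundleDocument` is a resolution-independent list of drawing
elements (paths, lines, text, rects) with explicit attributes.  SVG is the
canonical backend — one ``<path>`` element per sequence, carrying its exact
colour and opacity attributes, serialized deterministically so identical
inputs give byte-identical files.  PDF and PNG replay the same elements
through matplotlib.

Line darkness under normal (source-over) alpha compositing follows

    darkness(n) = 1 - (1 - opacity)^n

for n overlapping lines; :func:`effective_darkness` implements that model
and :func:`auto_opacity` inverts it to balance the per-line opacity against
the number of sequences, so a fully conserved stack reaches a target
darkness whether the alignment holds 9 sequences or 9000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

from .geometry import (
    Anchor,
    BundlePath,
    RenderSpec,
    anchor_layout,
    bezier_through,
    canvas_size,
    column_x,
    full_overlay_count,
    slot_y,
)
from .msa_io import GAP, AlignmentError, GroupedAlignment
from .profile_stats import (
    SelectionReport,
    bridge_counts,
    consensus,
    detect_threads,
    position_profile,
    summarize_groups,
)
from .scales import YAxisScale

_FMT = "%.2f"  # fixed coordinate precision => byte-stable output


def _fnum(v: float) -> str:
    return _FMT % v


def _gnum(v: float) -> str:
    """Compact number formatting for non-coordinate attributes (opacity)."""
    return f"{v:g}"


@dataclass(frozen=True)
class Element:
    """One drawing element: an SVG-like tag, attributes, optional text
    content, and non-rendered metadata (counts, roles) for inspection."""

    tag: str
    attrs: dict[str, str]
    text: Optional[str] = None
    meta: dict[str, Any] = field(default_factory=dict)

    def to_svg(self) -> str:
        parts = [f"<{self.tag}"]
        for k, v in self.attrs.items():
            parts.append(f' {k}="{v}"')
        if self.text is None:
            parts.append("/>")
        else:
            parts.append(f">{self.text}</{self.tag}>")
        return "".join(parts)


@dataclass(frozen=True)
class BundleDocument:
    width: float
    height: float
    elements: tuple[Element, ...]

    def paths(self) -> list[Element]:
        return [e for e in self.elements if e.tag == "path"]

    def to_svg(self) -> str:
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{_fnum(self.width)}" height="{_fnum(self.height)}" '
            f'viewBox="0 0 {_fnum(self.width)} {_fnum(self.height)}">\n'
        )
        body = "\n".join(e.to_svg() for e in self.elements)
        return head + body + "\n</svg>\n"


def effective_darkness(n_overlaps: int, opacity: float) -> float:
    """Resulting darkness of *n_overlaps* identical lines at *opacity*
    under normal blending: ``1 - (1 - opacity)**n``."""
    if n_overlaps < 0:
        raise ValueError("n_overlaps must be >= 0")
    if not 0 < opacity <= 1:
        raise ValueError("opacity must lie in (0, 1]")
    return 1.0 - (1.0 - opacity) ** n_overlaps


def auto_opacity(
    n_overlaps: int, target_darkness: float = 0.95
) -> float:
    """Per-line opacity at which *n_overlaps* stacked lines reach
    *target_darkness*; inverse of :func:`effective_darkness`."""
    if n_overlaps < 1:
        return 1.0
    if not 0 < target_darkness < 1:
        raise ValueError("target_darkness must lie in (0, 1)")
    return 1.0 - (1.0 - target_darkness) ** (1.0 / n_overlaps)


def _resolve_opacity(ga: GroupedAlignment, spec: RenderSpec) -> float:
    if spec.opacity is not None:
        return spec.opacity
    largest = max(g.size for g in ga.groups)
    layers = max(1, full_overlay_count(largest, spec.stack_size))
    return auto_opacity(layers)


def _segments_d(segs: Sequence[tuple[tuple[float, float], ...]]) -> str:
    (p0, c1, c2, p1) = segs[0]
    parts = [f"M {_fnum(p0[0])},{_fnum(p0[1])}"]
    for (_, c1, c2, p1) in segs:
        parts.append(
            f"C {_fnum(c1[0])},{_fnum(c1[1])} "
            f"{_fnum(c2[0])},{_fnum(c2[1])} "
            f"{_fnum(p1[0])},{_fnum(p1[1])}"
        )
    return " ".join(parts)


def _sequence_path_element(
    bp: BundlePath,
    color: str,
    opacity: float,
    spec: RenderSpec,
    role: str = "sequence",
) -> Element:
    segs = bp.bezier_segments()
    return Element(
        "path",
        {
            "d": _segments_d(segs),
            "fill": "none",
            "stroke": color,
            "stroke-width": _gnum(spec.line_thickness),
            "opacity": _gnum(opacity),
            "class": role,
        },
        meta={"row_index": bp.row_index, "segments": segs, "role": role},
    )


def _text(
    x: float, y: float, text: str, size: float, color: str = "#000000",
    anchor: str = "middle",
) -> Element:
    return Element(
        "text",
        {
            "x": _fnum(x),
            "y": _fnum(y),
            "font-family": "monospace",
            "font-size": _gnum(size),
            "fill": color,
            "text-anchor": anchor,
        },
        text=text,
    )


def _axes_elements(
    ga: GroupedAlignment, scale: YAxisScale, spec: RenderSpec
) -> tuple[list[Element], float]:
    """Y-axis residue letters (gap slot visibly separated), X-axis 1-based
    position numbers.  Returns the elements and the Y of the axis base."""
    els: list[Element] = []
    n_cols = ga.alignment.n_cols
    for slot, sym in enumerate(scale.order):
        y = slot_y(slot, scale, spec)
        label = "gap" if sym == GAP else sym
        els.append(
            _text(spec.margin - 10.0, y + 3.0, label, 9.0, anchor="end")
        )
    if scale.gap_slot < scale.n_slots - 1:
        # rule under the gap band, marking it off from the residue scale
        ysep = (
            slot_y(scale.gap_slot, scale, spec)
            + spec.effective_slot_height / 2.0
        )
        els.append(
            Element(
                "line",
                {
                    "x1": _fnum(spec.margin - 24.0),
                    "y1": _fnum(ysep),
                    "x2": _fnum(spec.margin),
                    "y2": _fnum(ysep),
                    "stroke": "#999999",
                    "stroke-width": "0.5",
                },
                meta={"role": "gap-separator"},
            )
        )
    base_y = (
        spec.margin
        + scale.n_slots * spec.effective_slot_height
        + spec.gap_slot_padding
        + 12.0
    )
    for c in range(1, n_cols + 1):
        els.append(_text(column_x(c, spec), base_y, str(c), 8.0))
    return els, base_y


def _legend_elements(
    ga: GroupedAlignment, spec: RenderSpec, y: float
) -> list[Element]:
    summary = summarize_groups(ga)
    parts = [
        f"{g.label}: {g.size}" for g in ga.groups
    ]
    text = (
        "n = " + ", ".join(parts)
        + f"; total {summary.total}"
        + f"; ratio {summary.ratio_string}"
    )
    return [
        _text(spec.margin, y, text, 9.0, anchor="start")
    ]


def render_bundle(
    ga: GroupedAlignment,
    scale: YAxisScale,
    spec: RenderSpec = RenderSpec(),
    highlight: Optional[SelectionReport] = None,
) -> BundleDocument:
    """Compose the Sequence Bundles document.

    One semi-opaque path per sequence, drawn in MSA order within each
    group and with groups composited in their declared order; optional
    highlight members are redrawn on top in the highlight colour at
    elevated opacity; per-group consensus rows and a legend carrying each
    group's sample size, the total and the 100:x ratio.
    """
    opacity = _resolve_opacity(ga, spec)
    width, height = canvas_size(ga.alignment.n_cols, scale, spec)
    els: list[Element] = [
        Element(
            "rect",
            {
                "x": "0",
                "y": "0",
                "width": _fnum(width),
                "height": _fnum(height),
                "fill": spec.background,
            },
            meta={"role": "background"},
        )
    ]
    axis_els, base_y = _axes_elements(ga, scale, spec)
    els.extend(axis_els)

    paths = anchor_layout(ga, scale, spec)
    by_row = {bp.row_index: bp for bp in paths}
    for gi, group in enumerate(ga.groups):
        for ri in group.row_indices:
            els.append(
                _sequence_path_element(
                    by_row[ri], group.color, opacity, spec
                )
            )
    if highlight is not None and highlight.size:
        id_to_row = {rid: i for i, rid in enumerate(ga.alignment.ids)}
        for rid in highlight.member_ids:
            els.append(
                _sequence_path_element(
                    by_row[id_to_row[rid]],
                    spec.highlight_color,
                    spec.highlight_opacity,
                    spec,
                    role="highlight",
                )
            )

    # consensus row per group, in the group colour, below the X labels
    y = base_y + 14.0
    for gi, group in enumerate(ga.groups):
        cons = consensus(ga, group.label, scale)
        for c, sym in enumerate(cons, start=1):
            els.append(
                _text(column_x(c, spec), y, sym, 9.0, color=group.color)
            )
        els.append(
            _text(spec.margin - 10.0, y, group.label, 8.0,
                  color=group.color, anchor="end")
        )
        y += 12.0
    els.extend(_legend_elements(ga, spec, y + 4.0))
    return BundleDocument(width, height, tuple(els))


def render_streamgraph(
    ga: GroupedAlignment,
    group: Optional[str],
    scale: YAxisScale,
    spec: RenderSpec = RenderSpec(),
    k: int = 3,
    min_support: float = 0.05,
    interval: Optional[tuple[int, int]] = None,
    overlay_threads: bool = False,
) -> BundleDocument:
    """Streamgraph variant: per column, a band for each of the top-k
    residues with thickness proportional to its count; between adjacent
    columns, ribbons with thickness proportional to the bridge joint
    count, ribbons below ``min_support x depth`` omitted.  Optionally
    overlays the extracted threads.
    """
    if k < 1:
        raise AlignmentError("k must be >= 1")
    if not 0 < min_support <= 1:
        raise AlignmentError("min_support must be in (0, 1]")
    n_cols = ga.alignment.n_cols
    start, end = interval if interval is not None else (1, n_cols)
    if not (1 <= start <= end <= n_cols):
        raise AlignmentError(f"interval ({start}, {end}) outside alignment")
    depth = len(ga.group_rows(group))
    width, height = canvas_size(n_cols, scale, spec)
    band_max = spec.effective_slot_height  # thickness of a unanimous band

    def thickness(count: int) -> float:
        return band_max * count / depth

    els: list[Element] = [
        Element(
            "rect",
            {"x": "0", "y": "0", "width": _fnum(width),
             "height": _fnum(height), "fill": spec.background},
            meta={"role": "background"},
        )
    ]
    axis_els, base_y = _axes_elements(ga, scale, spec)
    els.extend(axis_els)
    color = ga.group(group).color if group is not None else "#000000"

    tops: dict[int, list[tuple[str, int]]] = {}
    for p in range(start, end + 1):
        prof = position_profile(ga, group, p)
        ranked = sorted(prof.counts, key=lambda s: (-prof.counts[s], s))[:k]
        tops[p] = [(s, prof.counts[s]) for s in ranked]

    # ribbons first, bands on top
    for p in range(start, end):
        table = bridge_counts(ga, group, p)
        left = {s for s, _ in tops[p]}
        right = {s for s, _ in tops[p + 1]}
        for (a, b) in sorted(table.joint):
            c = table.joint[(a, b)]
            if a not in left or b not in right:
                continue
            if c < min_support * depth:
                continue
            pts = [
                (column_x(p, spec), slot_y(scale.slot_of(a), scale, spec)),
                (column_x(p + 1, spec), slot_y(scale.slot_of(b), scale, spec)),
            ]
            els.append(
                Element(
                    "path",
                    {
                        "d": _segments_d(bezier_through(pts)),
                        "fill": "none",
                        "stroke": color,
                        "stroke-width": _fnum(thickness(c)),
                        "opacity": "0.45",
                        "class": "ribbon",
                    },
                    meta={
                        "role": "ribbon",
                        "pair": (a, b),
                        "position": p,
                        "count": c,
                        "segments": bezier_through(pts),
                    },
                )
            )
    for p in range(start, end + 1):
        for sym, c in tops[p]:
            yc = slot_y(scale.slot_of(sym), scale, spec)
            th = thickness(c)
            els.append(
                Element(
                    "rect",
                    {
                        "x": _fnum(column_x(p, spec) - 3.0),
                        "y": _fnum(yc - th / 2.0),
                        "width": "6.00",
                        "height": _fnum(th),
                        "fill": color,
                        "class": "band",
                    },
                    meta={"role": "band", "symbol": sym, "position": p,
                          "count": c},
                )
            )
            els.append(
                _text(column_x(p, spec) + 8.0, yc + 3.0, sym, 8.0,
                      color="#555555", anchor="start")
            )
    if overlay_threads:
        ts = detect_threads(ga, group, (start, end), k=k,
                            min_support=min_support, scale=scale)
        for th_ in ts.threads:
            pts = [
                (column_x(start + i, spec),
                 slot_y(scale.slot_of(sym), scale, spec))
                for i, sym in enumerate(th_.residues)
            ]
            els.append(
                Element(
                    "path",
                    {
                        "d": _segments_d(bezier_through(pts)),
                        "fill": "none",
                        "stroke": spec.highlight_color,
                        "stroke-width": "1.5",
                        "opacity": "0.9",
                        "class": "thread",
                    },
                    meta={"role": "thread", "residues": th_.residues,
                          "segments": bezier_through(pts)},
                )
            )
    els.extend(_legend_elements(ga, spec, base_y + 18.0))
    return BundleDocument(width, height, tuple(els))


# --------------------------------------------------------------------------
# Export backends
# --------------------------------------------------------------------------

def _export_matplotlib(
    doc: BundleDocument, path: Path, format: str, png_scale: float
) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.path import Path as MplPath
    from matplotlib.patches import PathPatch, Rectangle

    dpi = 72.0
    fig = plt.figure(
        figsize=(doc.width / dpi, doc.height / dpi), dpi=dpi
    )
    ax = fig.add_axes((0, 0, 1, 1))
    ax.set_xlim(0, doc.width)
    ax.set_ylim(doc.height, 0)  # canvas Y grows downward
    ax.axis("off")
    for el in doc.elements:
        a = el.attrs
        if el.tag == "rect":
            ax.add_patch(
                Rectangle(
                    (float(a["x"]), float(a["y"])),
                    float(a["width"]), float(a["height"]),
                    facecolor=a.get("fill", "none"), edgecolor="none",
                )
            )
        elif el.tag == "line":
            ax.plot(
                [float(a["x1"]), float(a["x2"])],
                [float(a["y1"]), float(a["y2"])],
                color=a.get("stroke", "#000000"),
                linewidth=float(a.get("stroke-width", 1.0)),
            )
        elif el.tag == "path":
            segs = el.meta["segments"]
            verts = [segs[0][0]]
            codes = [MplPath.MOVETO]
            for (_, c1, c2, p1) in segs:
                verts.extend([c1, c2, p1])
                codes.extend([MplPath.CURVE4] * 3)
            ax.add_patch(
                PathPatch(
                    MplPath(verts, codes),
                    fill=False,
                    edgecolor=a.get("stroke", "#000000"),
                    linewidth=float(a.get("stroke-width", 1.0)),
                    alpha=float(a.get("opacity", 1.0)),
                )
            )
        elif el.tag == "text":
            ha = {"middle": "center", "end": "right", "start": "left"}[
                a.get("text-anchor", "start")
            ]
            ax.text(
                float(a["x"]), float(a["y"]), el.text or "",
                fontsize=float(a.get("font-size", 9.0)),
                color=a.get("fill", "#000000"),
                family="monospace", ha=ha, va="baseline",
            )
    if format == "png":
        fig.savefig(path, format="png", dpi=dpi * png_scale)
    else:
        fig.savefig(path, format="pdf")
    plt.close(fig)


def export(
    doc: BundleDocument,
    path: Union[str, Path],
    format: str = "svg",
    png_scale: float = 1.0,
) -> None:
    """Write the document as ``svg`` (canonical, deterministic), ``pdf``
    or ``png`` (rasterized at ``png_scale`` pixels per canvas unit)."""
    path = Path(path)
    if format == "svg":
        path.write_text(doc.to_svg())
    elif format in ("pdf", "png"):
        _export_matplotlib(doc, path, format, png_scale)
    else:
        raise ValueError(f"unknown export format {format!r}")
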