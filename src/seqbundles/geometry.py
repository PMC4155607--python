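"""Layout of the bundle: each sequence becomes one unbroken path of
per-column anchors on the (column, Y-slot) grid, stacked within slots and
smoothed into a curve that flattens at every site.

Coordinate convention: canvas Y increases downward; slot 0 (the top of the
Y-axis scale) is at the top of the plot.

Stacking ("sets of 10"): within each group, and within each (column, slot)
cell independently, the j-th group sequence (in MSA order) to visit the
cell takes stack offset ``j mod stack_size``; further lines overlay earlier
offsets exactly, which is what deepens the bundle's opacity.  886 lines
sharing one cell at stack size 10 give floor(886/10) = 88 complete overlay
layers.

Smoothing: between consecutive anchors the curve is the cubic Hermite
segment with zero slope at both ends, written as a cubic Bezier whose
control handles are horizontal and one third of the column spacing long.
That interpolant is monotone between anchors (no vertical overshoot) and
horizontal at every site, so stacks of lines converge flat and read as a
single bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .msa_io import AlignmentError, GroupedAlignment
from .scales import YAxisScale


@dataclass(frozen=True)
class RenderSpec:
    """Every visual parameter of a bundle render.

    ``opacity`` is the per-line alpha in normal (source-over) compositing;
    the reference figures use 0.02 (98% transparency).  Set it to None to
    auto-balance against the number of sequences (see
    :func:`seqbundles.render.auto_opacity`).  ``group_offset_step`` is the
    vertical shift between successive groups, in canvas units; by default
    one line thickness, so sub-bundles sit side by side without occluding
    each other.
    """

    line_thickness: float = 1.2          # canvas units (pt)
    opacity: Optional[float] = 0.02      # None => auto-balanced
    stack_size: int = 10
    slot_height: Optional[float] = None  # default: 12 x line_thickness
    group_offset_step: Optional[float] = None  # default: line_thickness
    column_width: float = 24.0
    gap_slot_padding: float = 6.0        # extra separation of the gap slot
    margin: float = 36.0
    highlight_color: str = "#E8336D"
    highlight_opacity: float = 0.8
    background: str = "#FFFFFF"
    png_scale: float = 2.0               # raster pixels per canvas unit

    def __post_init__(self) -> None:
        if self.opacity is not None and not 0 < self.opacity <= 1:
            raise ValueError("opacity must lie in (0, 1]")
        if self.stack_size < 1:
            raise ValueError("stack_size must be >= 1")
        if self.line_thickness <= 0:
            raise ValueError("line_thickness must be positive")
        if (
            self.slot_height is not None
            and self.stack_size * self.line_thickness > self.slot_height
        ):
            raise ValueError("stack of lines does not fit in its slot")

    @property
    def effective_slot_height(self) -> float:
        if self.slot_height is not None:
            return self.slot_height
        # 10-line stack plus 2 lines of padding by default
        return (self.stack_size + 2) * self.line_thickness

    @property
    def effective_group_step(self) -> float:
        if self.group_offset_step is not None:
            return self.group_offset_step
        return self.line_thickness


@dataclass(frozen=True)
class Anchor:
    column: int        # 1-based alignment column
    slot: int          # Y-axis slot index on the active scale
    stack_offset: int  # 0 .. stack_size-1 within the (column, slot) cell
    x: float           # canvas coordinates of the anchor point
    y: float


@dataclass(frozen=True)
class BundlePath:
    """One sequence's full geometry: exactly one anchor per column."""

    row_index: int
    group_index: int
    anchors: tuple[Anchor, ...]

    def bezier_segments(self) -> list[tuple[tuple[float, float], ...]]:
        """Cubic Bezier segments (p0, c1, c2, p1) through all anchors,
        horizontal-tangent at each; a single anchor degenerates to a
        horizontal tick one column width wide centred on it."""
        pts = [(a.x, a.y) for a in self.anchors]
        return bezier_through(pts)


def bezier_through(
    pts: Sequence[tuple[float, float]]
) -> list[tuple[tuple[float, float], ...]]:
    """Zero-slope cubic Hermite interpolation through *pts*, emitted as
    cubic Bezier control quadruples."""
    if len(pts) == 1:
        (x, y) = pts[0]
        # degenerate: a horizontal tick of one inter-column width
        half = 12.0
        return [((x - half, y), (x - half / 3, y), (x + half / 3, y),
                 (x + half, y))]
    segs = []
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        dx = (x1 - x0) / 3.0
        segs.append(((x0, y0), (x0 + dx, y0), (x1 - dx, y1), (x1, y1)))
    return segs


def evaluate_segment(
    seg: tuple[tuple[float, float], ...], t: float
) -> tuple[float, float]:
    """Point on one cubic Bezier segment at parameter t in [0, 1]."""
    (p0, c1, c2, p1) = seg
    u = 1 - t
    x = u**3 * p0[0] + 3 * u**2 * t * c1[0] + 3 * u * t**2 * c2[0] + t**3 * p1[0]
    y = u**3 * p0[1] + 3 * u**2 * t * c1[1] + 3 * u * t**2 * c2[1] + t**3 * p1[1]
    return x, y


def full_overlay_count(n_lines: int, stack_size: int) -> int:
    """Complete overlay layers when *n_lines* share one (column, slot)
    cell: floor(n_lines / stack_size)."""
    if stack_size < 1:
        raise ValueError("stack_size must be >= 1")
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    return n_lines // stack_size


def column_x(p: int, spec: RenderSpec) -> float:
    """Canvas X of 1-based column *p*."""
    return spec.margin + (p - 0.5) * spec.column_width


def slot_y(slot: int, scale: YAxisScale, spec: RenderSpec) -> float:
    """Canvas Y of a slot's centre line; the gap slot band gets extra
    padding so it reads as a separate unit of the axis."""
    h = spec.effective_slot_height
    y = spec.margin + (slot + 0.5) * h
    # slots below the gap slot are pushed down, separating the gap band
    if slot > scale.gap_slot:
        y += spec.gap_slot_padding
    elif slot == scale.gap_slot:
        y += spec.gap_slot_padding / 2.0
    return y


def group_offset_layout(
    ga: GroupedAlignment, spec: RenderSpec
) -> tuple[float, ...]:
    """Vertical shift per group: group g is shifted by g x step, applied
    after slot placement so sub-bundles sit staggered but aligned."""
    if not ga.groups:
        raise AlignmentError("no groups")
    step = spec.effective_group_step
    return tuple(g * step for g in range(len(ga.groups)))


def canvas_size(
    n_cols: int, scale: YAxisScale, spec: RenderSpec
) -> tuple[float, float]:
    width = 2 * spec.margin + n_cols * spec.column_width
    height = (
        2 * spec.margin
        + scale.n_slots * spec.effective_slot_height
        + spec.gap_slot_padding
        + 40.0  # consensus + legend strip below the X-axis
    )
    return width, height


def anchor_layout(
    ga: GroupedAlignment, scale: YAxisScale, spec: RenderSpec
) -> list[BundlePath]:
    """Compute every sequence's anchors: slot from the scale, stack offset
    from per-cell arrival order within the group, canvas point from the
    grid plus the group's vertical shift.

    Deterministic: identical inputs give an identical layout.  No sequence
    is ever dropped or truncated — each path has exactly n_cols anchors.
    """
    offsets = group_offset_layout(ga, spec)
    t = spec.line_thickness
    paths: list[BundlePath] = []
    for gi, group in enumerate(ga.groups):
        cell_fill: dict[tuple[int, int], int] = {}
        for ri in group.row_indices:
            row = ga.alignment.rows[ri]
            anchors = []
            for c, sym in enumerate(row, start=1):
                slot = scale.slot_of(sym)
                j = cell_fill.get((c, slot), 0)
                cell_fill[(c, slot)] = j + 1
                stack_offset = j % spec.stack_size
                # stack centred on the slot's centre line
                stagger = (stack_offset - (spec.stack_size - 1) / 2.0) * t
                anchors.append(
                    Anchor(
                        column=c,
                        slot=slot,
                        stack_offset=stack_offset,
                        x=column_x(c, spec),
                        y=slot_y(slot, scale, spec) + stagger + offsets[gi],
                    )
                )
            paths.append(BundlePath(ri, gi, tuple(anchors)))
    # emit in global MSA order so drawing order is stable and documented
    paths.sort(key=lambda p: (p.group_index, p.row_index))
    return paths
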